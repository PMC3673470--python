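"""Hypothesis-family bookkeeping and multiple-testing correction.

Related null-hypothesis tests on the same locus are grouped into
*hypothesis families* and corrected together.  The default correction is
the Benjamini–Hochberg step-up false-discovery-rate procedure; Holm's
step-down method is available as an alternative.  Families may overlap:
one data set's tests can be members of two families (e.g. when a locus is
compared both within its own family and against sibling regions), in
which case it receives a family-specific adjusted p-value in each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_fdr",
    "holm",
    "adjust",
    "HypothesisFamily",
    "build_test_families",
    "enumerate_tests",
    "ManifestError",
]


class ManifestError(ValueError):
    """A study manifest references undefined data sets or tests."""


def _validate_p(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p-values must be a 1-D vector")
    if arr.size and (np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr))):
        raise ValueError("p-values must lie in [0, 1]")
    return arr


def bh_fdr(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Sort ascending, set ``adj_(i) = p_(i) * m / i``, enforce monotonicity
    from the largest rank downward, cap at 1.  Ties share adjusted values
    through the stable sort.
    """
    arr = _validate_p(p_raw)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def holm(p_raw) -> np.ndarray:
    """Holm step-down adjusted p-values, in input order."""
    arr = _validate_p(p_raw)
    if arr.size == 0:
        return arr
    return multipletests(arr, method="holm")[1]


def adjust(p_raw, method: str = "BH") -> np.ndarray:
    """Dispatch on correction name: ``"BH"`` (default) or ``"Holm"``."""
    if method.upper() == "BH":
        return bh_fdr(p_raw)
    if method.lower() == "holm":
        return holm(p_raw)
    raise ValueError(f"unknown correction {method!r}")


@dataclass
class HypothesisFamily:
    """A group of related tests corrected together.

    ``member_tests`` are (data set id, test name) pairs; ``p_raw`` and
    ``p_adj`` align with them once p-values are attached.
    """

    family_id: str
    member_tests: list[tuple[str, str]]
    p_raw: np.ndarray = field(default_factory=lambda: np.array([]))
    p_adj: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def size(self) -> int:
        return len(self.member_tests)

    def attach(self, p_by_test: dict[tuple[str, str], float], method: str = "BH") -> None:
        """Look up each member's raw p-value and adjust within the family."""
        missing = [m for m in self.member_tests if m not in p_by_test]
        if missing:
            raise ManifestError(f"family {self.family_id}: no p-value for {missing}")
        self.p_raw = np.array([p_by_test[m] for m in self.member_tests])
        self.p_adj = adjust(self.p_raw, method)


def enumerate_tests(manifest: dict) -> list[tuple[str, str]]:
    """All distinct (data set, test) pairs, in manifest order."""
    seen: list[tuple[str, str]] = []
    for ds in manifest.get("datasets", []):
        for test in ds.get("tests", []):
            pair = (ds["id"], test)
            if pair in seen:
                raise ManifestError(f"test {pair} declared twice")
            seen.append(pair)
    return seen


def build_test_families(manifest: dict) -> list[HypothesisFamily]:
    """Construct hypothesis families from a study manifest.

    The manifest carries ``datasets`` (each with ``id`` and a ``tests``
    list) and ``families`` mapping family id to a list of
    ``[data set id, test name]`` members.  Every member must resolve to a
    declared test; overlap between families is permitted.
    """
    declared = set(enumerate_tests(manifest))
    families: list[HypothesisFamily] = []
    for fam_id, members in manifest.get("families", {}).items():
        pairs = [tuple(m) for m in members]
        unknown = [m for m in pairs if m not in declared]
        if unknown:
            raise ManifestError(
                f"family {fam_id!r} references undeclared tests: {unknown}"
            )
        families.append(HypothesisFamily(str(fam_id), pairs))
    return families
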