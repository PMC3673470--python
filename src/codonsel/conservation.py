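"""Conservation-index scoring and disease-mutation mapping.

From the per-site posterior omega-class probabilities of a fitted site
model, each amino-acid site receives a weighted mean ratio
``omega_bar = sum_k PP_k * omega_k``.  Sites under purifying selection
(``omega_bar < 1``) get a conservation index ``CI = 1 - omega_bar``; sites
at or above neutrality get ``CI = 0``.  Separately, each site is assigned
its *minimum-omega category*: posterior mass is accumulated from the
lowest omega class upward, and the first class at which the cumulative
probability exceeds 0.95 defines the category; categories with
``omega < 0.25`` mark significant purifying selection.

Disease-associated mutations (DAMs) given in 1-based protein coordinates
of a named reference sequence are mapped through reference gaps onto
alignment columns and annotated with the conservation profile, enabling
the overlap summaries used to ask whether known disease variants fall at
evolutionarily conserved sites.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import SitePosteriors
from .codons import MISSING, CodonAlignment

__all__ = [
    "ConservationProfile",
    "DAMRecord",
    "weighted_mean_omega",
    "conservation_index",
    "min_omega_category",
    "conservation_profile",
    "map_dams",
    "dam_overlap_summary",
    "read_dam_table",
]

logger = logging.getLogger(__name__)

DAM_COLUMNS = ["gene", "protein_position", "ref_aa", "alt_aa", "source_id", "external_score"]


def weighted_mean_omega(post: SitePosteriors) -> np.ndarray:
    """Posterior-weighted mean omega per site: ``sum_k PP_k * omega_k``."""
    return post.PP @ post.class_omegas


def conservation_index(omega_bar: np.ndarray) -> np.ndarray:
    """``1 - omega_bar`` where ``omega_bar < 1``, else 0."""
    ob = np.asarray(omega_bar, float)
    if np.any(ob < 0):
        raise ValueError("negative weighted mean omega — upstream invariant breached")
    return np.where(ob < 1.0, 1.0 - ob, 0.0)


def min_omega_category(
    post: SitePosteriors,
    pp_threshold: float = 0.95,
    low_omega: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-omega significance category per site.

    Classes must be ordered by non-decreasing omega.  Posterior
    probabilities are accumulated starting from the lowest class; the
    first class whose cumulative PP exceeds ``pp_threshold`` is the site's
    category (falling back to the top class if the threshold is never
    crossed).  A site is flagged ``significant_purifying`` when its
    category omega is below ``low_omega``.

    Returns ``(class index, class omega, significant flag)`` arrays.
    """
    om = post.class_omegas
    if np.any(np.diff(om) < -1e-12):
        raise ValueError("classes must be ordered by increasing omega")
    cum = np.cumsum(post.PP, axis=1)
    exceeded = cum > pp_threshold
    # argmax finds the first True; rows with none (numerical slack) -> top class
    idx = np.where(exceeded.any(axis=1), exceeded.argmax(axis=1), post.n_classes - 1)
    values = om[idx]
    return idx, values, values < low_omega


@dataclass
class ConservationProfile:
    """Per-site conservation measures in alignment (and reference) coordinates.

    ``reference_position[s]`` is the 1-based ungapped protein coordinate of
    alignment column ``s+1`` in the designated reference sequence, or -1
    where the reference is gapped/unobserved.
    """

    omega_bar: np.ndarray
    ci: np.ndarray
    min_omega_class: np.ndarray
    min_omega_value: np.ndarray
    significant_purifying: np.ndarray
    reference_position: np.ndarray
    gene: str = ""
    reference_name: str | None = None

    @property
    def n_sites(self) -> int:
        return int(self.omega_bar.size)

    def to_frame(self) -> pd.DataFrame:
        """One row per alignment column, 1-based coordinates, NA for gaps."""
        refpos = pd.array(
            [p if p > 0 else pd.NA for p in self.reference_position], dtype="Int64"
        )
        return pd.DataFrame(
            {
                "gene": self.gene,
                "alignment_column": np.arange(1, self.n_sites + 1),
                "reference_position": refpos,
                "omega_bar": self.omega_bar,
                "ci": self.ci,
                "min_omega_class": self.min_omega_class + 1,
                "min_omega_value": self.min_omega_value,
                "significant_purifying": self.significant_purifying,
            }
        )


def _reference_positions(aln: CodonAlignment) -> np.ndarray:
    """1-based ungapped protein coordinate per column; -1 at reference gaps."""
    if aln.reference_name is None:
        raise ValueError("alignment has no designated reference taxon")
    ref = aln.row(aln.reference_name)
    out = np.full(aln.n_sites, -1, dtype=np.int64)
    pos = 0
    for s, state in enumerate(ref):
        if state != MISSING:
            pos += 1
            out[s] = pos
    return out


def conservation_profile(
    post: SitePosteriors,
    aln: CodonAlignment | None = None,
    gene: str = "",
    pp_threshold: float = 0.95,
    low_omega: float = 0.25,
) -> ConservationProfile:
    """Assemble the full per-site profile from posteriors (and a reference)."""
    ob = weighted_mean_omega(post)
    ci = conservation_index(ob)
    idx, values, flags = min_omega_category(post, pp_threshold, low_omega)
    if aln is not None and aln.reference_name is not None:
        refpos = _reference_positions(aln)
        if aln.n_sites != post.n_sites:
            raise ValueError("alignment and posteriors disagree on site count")
    else:
        refpos = np.arange(1, post.n_sites + 1, dtype=np.int64)
    return ConservationProfile(
        ob, ci, idx, values, flags, refpos,
        gene=gene,
        reference_name=None if aln is None else aln.reference_name,
    )


@dataclass
class DAMRecord:
    """A disease-associated missense mutation at a reference protein position."""

    gene: str
    protein_position: int
    ref_aa: str
    alt_aa: str
    source_id: str = ""
    external_score: float | None = None
    mapped_column: int | None = None
    mapped_ci: float | None = None

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise ValueError("protein_position is 1-based and must be >= 1")
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa and alt_aa must differ (missense change)")


def read_dam_table(text_or_path) -> pd.DataFrame:
    """Read a DAM TSV (gene, protein_position, ref_aa, alt_aa, source_id,
    external_score); the last two columns are optional."""
    if isinstance(text_or_path, str) and "\t" in text_or_path:
        handle = io.StringIO(text_or_path)
    else:
        handle = text_or_path
    df = pd.read_csv(handle, sep="\t", comment="#")
    for col in ("source_id", "external_score"):
        if col not in df.columns:
            df[col] = pd.NA
    required = {"gene", "protein_position", "ref_aa", "alt_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DAM table missing columns: {sorted(missing)}")
    return df[DAM_COLUMNS]


def map_dams(
    dams: pd.DataFrame,
    aln: CodonAlignment,
    profile: ConservationProfile,
) -> pd.DataFrame:
    """Map DAM protein positions through reference gaps onto the profile.

    Adds ``mapped_column`` (1-based alignment column), ``mapped_ci``,
    ``mapped_omega_bar``, ``min_omega_value``, ``significant_purifying``
    and ``ref_aa_match`` columns.  Positions beyond the reference's
    ungapped length are skipped with a logged error; reference amino-acid
    mismatches are flagged but kept.
    """
    refpos = _reference_positions(aln)
    col_of = {int(p): s for s, p in enumerate(refpos) if p > 0}
    ref_aa_seq = aln.translate_row(aln.reference_name)
    rows = []
    for rec in dams.itertuples(index=False):
        pos = int(rec.protein_position)
        if pos < 1 or pos not in col_of:
            logger.error(
                "DAM %s at protein position %d exceeds reference length %d; skipped",
                getattr(rec, "source_id", "") or f"{rec.gene}:{rec.ref_aa}{pos}{rec.alt_aa}",
                pos,
                max(col_of) if col_of else 0,
            )
            continue
        s = col_of[pos]
        row = rec._asdict()
        row["mapped_column"] = s + 1
        row["mapped_ci"] = float(profile.ci[s])
        row["mapped_omega_bar"] = float(profile.omega_bar[s])
        row["min_omega_value"] = float(profile.min_omega_value[s])
        row["significant_purifying"] = bool(profile.significant_purifying[s])
        row["ref_aa_match"] = ref_aa_seq[s] == str(rec.ref_aa)
        if not row["ref_aa_match"]:
            logger.warning(
                "DAM at position %d: reference residue %s differs from table's %s",
                pos, ref_aa_seq[s], rec.ref_aa,
            )
        rows.append(row)
    columns = DAM_COLUMNS + [
        "mapped_column", "mapped_ci", "mapped_omega_bar",
        "min_omega_value", "significant_purifying", "ref_aa_match",
    ]
    return pd.DataFrame(rows, columns=columns)


def dam_overlap_summary(mapped: pd.DataFrame, ci_threshold: float = 0.9) -> pd.DataFrame:
    """Count DAMs at/above the conservation-index threshold, per gene and overall."""
    def _summarize(group: pd.DataFrame, label: str) -> dict:
        n = len(group)
        high = int((group["mapped_ci"] >= ci_threshold).sum()) if n else 0
        return {
            "gene": label,
            "n_dams": n,
            "n_ci_at_or_above": high,
            "n_ci_below": n - high,
            "prop_ci_at_or_above": (high / n) if n else np.nan,
            "ci_threshold": ci_threshold,
        }

    rows = [
        _summarize(g, gene) for gene, g in mapped.groupby("gene", sort=True)
    ] if len(mapped) else []
    rows.append(_summarize(mapped, "ALL"))
    return pd.DataFrame(rows)
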