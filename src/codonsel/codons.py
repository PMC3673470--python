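"""Codon state space, alignment I/O, equilibrium frequencies and rate matrices.

The machinery here is shared by every selection model in the package: a
Goldman–Yang style codon substitution process on the 61 sense codons of the
standard genetic code, parameterized by the transition/transversion rate
ratio ``kappa`` and the nonsynonymous/synonymous rate ratio ``omega`` (dN/dS).

Codons are indexed lexicographically over the nucleotide alphabet T, C, A, G
(the dominant ordering convention in codon-model software); all matrices in
the package use this ordering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MISSING",
    "GeneticCode",
    "CodonAlignment",
    "CodonFrequencies",
    "RateMatrix",
    "standard_code",
    "read_codon_alignment",
    "write_codon_alignment",
    "codon_frequencies",
    "build_rate_matrix",
    "transition_matrix",
    "FrameError",
    "StopCodonError",
    "AlignmentInputError",
    "ParameterError",
]

#: Sentinel state for a codon column that is gapped or ambiguous in a taxon.
MISSING: int = -1

NUCLEOTIDES = "TCAG"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class StopCodonError(ValueError):
    """A stop codon was found inside a coding sequence."""


class AlignmentInputError(ValueError):
    """Malformed alignment input (duplicate taxa, empty data, ...)."""


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table plus the derived sense-codon indexing.

    Parameters
    ----------
    table
        Map from all 64 nucleotide triplets (T/C/A/G alphabet) to one-letter
        amino-acid symbols, with ``"*"`` for stops.
    """

    table: dict[str, str]
    sense_codons: tuple[str, ...] = field(init=False)
    stop_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must map 64 triplets, got {len(self.table)}")
        triplets = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
        if set(triplets) != set(self.table):
            raise ValueError("genetic code table keys must be the 64 T/C/A/G triplets")
        object.__setattr__(
            self, "sense_codons", tuple(t for t in triplets if self.table[t] != "*")
        )
        object.__setattr__(
            self, "stop_codons", tuple(t for t in triplets if self.table[t] == "*")
        )

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def index(self, codon: str) -> int:
        """Sense-codon index of ``codon`` (raises KeyError for stops/ambiguity)."""
        return self._codon_index[codon]

    @property
    def _codon_index(self) -> dict[str, int]:
        idx = self.__dict__.get("_codon_index_cache")
        if idx is None:
            idx = {c: i for i, c in enumerate(self.sense_codons)}
            self.__dict__["_codon_index_cache"] = idx
        return idx

    def translate(self, codon: str) -> str:
        return self.table[codon]

    def amino_acids(self) -> np.ndarray:
        """Amino-acid symbol per sense-codon index."""
        return np.array([self.table[c] for c in self.sense_codons])

    def structure(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Single-step change classification among sense codons.

        Returns boolean (n,n) arrays ``(single, transition, synonymous)``:
        ``single[i,j]`` is True when codons i and j differ at exactly one
        position; the other two arrays classify that single change.
        """
        cached = self.__dict__.get("_structure_cache")
        if cached is not None:
            return cached
        n = self.n_states
        single = np.zeros((n, n), dtype=bool)
        trans = np.zeros((n, n), dtype=bool)
        syn = np.zeros((n, n), dtype=bool)
        for i, ci in enumerate(self.sense_codons):
            for j, cj in enumerate(self.sense_codons):
                if i == j:
                    continue
                diffs = [k for k in range(3) if ci[k] != cj[k]]
                if len(diffs) != 1:
                    continue
                k = diffs[0]
                single[i, j] = True
                trans[i, j] = _is_transition(ci[k], cj[k])
                syn[i, j] = self.table[ci] == self.table[cj]
        self.__dict__["_structure_cache"] = (single, trans, syn)
        return single, trans, syn


def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (61 sense codons, 3 stops)."""
    table = {}
    for a in NUCLEOTIDES:
        for b in NUCLEOTIDES:
            for c in NUCLEOTIDES:
                triplet = a + b + c
                table[triplet] = str(Seq(triplet).translate(table=1))
    return GeneticCode(table)


_STANDARD = None


def _default_code() -> GeneticCode:
    global _STANDARD
    if _STANDARD is None:
        _STANDARD = standard_code()
    return _STANDARD


@dataclass
class CodonAlignment:
    """An in-frame codon alignment: taxa x sites over sense-codon indices.

    ``states[i, s]`` is the sense-codon index of taxon ``i`` at codon site
    ``s``, or :data:`MISSING` for a gapped/ambiguous triplet.
    """

    taxa: list[str]
    states: np.ndarray
    code: GeneticCode
    reference_name: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int32)
        if self.states.ndim != 2:
            raise AlignmentInputError("states must be a 2-D taxa x sites array")
        if self.states.shape[0] != len(self.taxa):
            raise AlignmentInputError("row count does not match taxon count")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentInputError("duplicate taxon names in alignment")
        if self.states.size and (
            self.states.max() >= self.code.n_states or self.states.min() < MISSING
        ):
            raise AlignmentInputError("codon state out of range")
        if self.reference_name is not None and self.reference_name not in self.taxa:
            raise AlignmentInputError(f"reference taxon {self.reference_name!r} not in alignment")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.states.shape[1])

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def subset_taxa(self, names: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(n) for n in names]
        ref = self.reference_name if self.reference_name in names else None
        return CodonAlignment(list(names), self.states[idx], self.code, ref)

    def translate_row(self, taxon: str) -> str:
        """Amino-acid string for one taxon, 'X' at missing sites."""
        aa = self.code.amino_acids()
        return "".join("X" if s == MISSING else aa[s] for s in self.row(taxon))

    def to_fasta(self) -> str:
        records = []
        for i, name in enumerate(self.taxa):
            seq = "".join(
                "---" if s == MISSING else self.code.sense_codons[s]
                for s in self.states[i]
            )
            records.append(SeqRecord(Seq(seq), id=name, description=""))
        buf = io.StringIO()
        SeqIO.write(records, buf, "fasta")
        return buf.getvalue()


def read_codon_alignment(
    fasta_text: str,
    code: GeneticCode | None = None,
    missing_policy: str = "mask",
    reference_name: str | None = None,
) -> CodonAlignment:
    """Read an in-frame FASTA alignment into codon states.

    Every sequence must have length divisible by three and equal to the
    others.  Under the default ``missing_policy="mask"``, any triplet
    containing a gap or non-ACGT character becomes :data:`MISSING`;
    ``"strict"`` raises instead.  Stop codons are rejected outright — the
    alignments this package consumes are screened coding sequence in which
    no nonsense mutations are expected.
    """
    if code is None:
        code = _default_code()
    if missing_policy not in ("mask", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if not records:
        raise AlignmentInputError("no FASTA records found")
    taxa: list[str] = []
    rows: list[list[int]] = []
    length = None
    for rec in records:
        name = rec.id
        if name in taxa:
            raise AlignmentInputError(f"duplicate taxon name {name!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if len(seq) % 3 != 0:
            raise FrameError(
                f"sequence {name!r} has length {len(seq)}, not a multiple of 3"
            )
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentInputError(
                f"sequence {name!r} length {len(seq)} differs from first record ({length})"
            )
        row = []
        for s in range(0, len(seq), 3):
            triplet = seq[s : s + 3]
            if any(ch not in "ACGT" for ch in triplet):
                if missing_policy == "strict":
                    raise AlignmentInputError(
                        f"ambiguous triplet {triplet!r} in {name!r} at codon site {s // 3 + 1}"
                    )
                row.append(MISSING)
                continue
            if code.table[triplet] == "*":
                raise StopCodonError(
                    f"stop codon {triplet!r} in taxon {name!r} at codon site {s // 3 + 1}"
                )
            row.append(code.index(triplet))
        taxa.append(name)
        rows.append(row)
    states = np.array(rows, dtype=np.int32) if rows else np.zeros((0, 0), np.int32)
    return CodonAlignment(taxa, states, code, reference_name)


def write_codon_alignment(aln: CodonAlignment) -> str:
    """Serialize an alignment back to FASTA (MISSING becomes ``---``)."""
    return aln.to_fasta()


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium sense-codon frequencies pi and the estimator that made them."""

    pi: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if np.any(pi < 0):
            raise ParameterError("codon frequencies must be non-negative")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ParameterError("codon frequencies must sum to 1")


def codon_frequencies(
    aln: CodonAlignment | None,
    mode: str = "F3x4",
    pseudocount: float = 0.5,
    code: GeneticCode | None = None,
) -> CodonFrequencies:
    """Estimate equilibrium codon frequencies from an alignment.

    Modes: ``uniform`` (1/61 each), ``F1x4`` / ``F3x4`` (products of overall
    or position-specific nucleotide frequencies, renormalized over sense
    codons), ``F61`` (observed codon proportions, smoothed with
    ``pseudocount`` added to every sense codon).  MISSING entries are
    ignored by the empirical modes.
    """
    if code is None:
        code = aln.code if aln is not None else _default_code()
    n = code.n_states
    if mode == "uniform":
        return CodonFrequencies(np.full(n, 1.0 / n), mode)
    if aln is None or aln.n_sites == 0 or aln.n_taxa == 0:
        raise AlignmentInputError(f"empirical frequency mode {mode!r} needs a non-empty alignment")
    observed = aln.states[aln.states >= 0]
    if observed.size == 0:
        raise AlignmentInputError("alignment contains no observed codons")
    if mode == "F61":
        counts = np.bincount(observed, minlength=n).astype(float) + pseudocount
        return CodonFrequencies(counts / counts.sum(), mode)
    if mode in ("F1x4", "F3x4"):
        # nucleotide counts, per codon position for F3x4, pooled for F1x4
        nt_index = {c: i for i, c in enumerate(NUCLEOTIDES)}
        counts = np.zeros((3, 4))
        for state in observed:
            codon = code.sense_codons[state]
            for pos in range(3):
                counts[pos, nt_index[codon[pos]]] += 1
        if mode == "F1x4":
            pooled = counts.sum(axis=0)
            freq = np.tile(pooled / pooled.sum(), (3, 1))
        else:
            freq = counts / counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                freq[0, nt_index[c[0]]] * freq[1, nt_index[c[1]]] * freq[2, nt_index[c[2]]]
                for c in code.sense_codons
            ]
        )
        total = pi.sum()
        if total <= 0:
            raise AlignmentInputError("degenerate nucleotide frequencies")
        return CodonFrequencies(pi / total, mode)
    raise ValueError(f"unknown frequency mode {mode!r}")


class RateMatrix:
    """Instantaneous codon rate matrix Q for one (kappa, omega) class.

    Off-diagonal entries follow the Goldman–Yang form: zero for multi-
    nucleotide changes, otherwise proportional to the target frequency
    ``pi_j``, times ``kappa`` for transitions and ``omega`` for
    nonsynonymous changes.  By default Q is scaled so the expected
    substitution rate at equilibrium, ``-sum_i pi_i q_ii``, is one
    substitution per codon per unit branch length; mixture models rescale
    all class matrices by a common mixture-weighted factor instead.
    """

    def __init__(
        self,
        kappa: float,
        omega: float,
        pi: CodonFrequencies,
        code: GeneticCode | None = None,
        scale: bool = True,
        eig_cache: dict | None = None,
    ) -> None:
        if kappa <= 0:
            raise ParameterError(f"kappa must be positive, got {kappa}")
        if omega < 0:
            raise ParameterError(f"omega must be non-negative, got {omega}")
        self.kappa = float(kappa)
        self.omega = float(omega)
        self.pi = pi
        self.code = code if code is not None else _default_code()
        p = np.asarray(pi.pi, dtype=float)
        key = (self.kappa, self.omega)
        cached = eig_cache.get(key) if eig_cache is not None else None
        if cached is None:
            single, trans, syn = self.code.structure()
            Q = np.where(single, p[None, :], 0.0)
            Q = Q * np.where(trans, self.kappa, 1.0)
            Q = Q * np.where(single & ~syn, self.omega, 1.0)
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            rate = float(-(p * np.diag(Q)).sum())
            cached = {"Q_raw": Q, "rate": rate, "eig": None}
            if eig_cache is not None:
                if len(eig_cache) > 512:
                    eig_cache.clear()
                eig_cache[key] = cached
        self._cached = cached
        self.unscaled_rate = cached["rate"]
        self._factor = 1.0
        if scale and self.unscaled_rate > 0:
            self._factor = 1.0 / self.unscaled_rate
        self._use_expm = bool(np.any(p <= 0))

    @property
    def Q(self) -> np.ndarray:
        """The (scaled) instantaneous rate matrix."""
        return self._cached["Q_raw"] * self._factor

    def rescale(self, factor: float) -> "RateMatrix":
        """Divide Q by ``factor`` in place (mixture-level normalisation)."""
        if factor <= 0:
            raise ParameterError("scale factor must be positive")
        self._factor /= factor
        return self

    def _eigendecompose(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # Reversible Q is similar to a symmetric matrix via diag(sqrt(pi));
        # the decomposition is of the *unscaled* Q, so it survives rescaling.
        if self._cached["eig"] is None:
            p = np.asarray(self.pi.pi, dtype=float)
            d = np.sqrt(p)
            S = (self._cached["Q_raw"] * d[:, None]) / d[None, :]
            S = 0.5 * (S + S.T)
            lam, V = np.linalg.eigh(S)
            left = V.T * d[None, :]        # V^T D
            right = V / d[:, None]         # D^-1 V
            self._cached["eig"] = (lam, right, left)
        return self._cached["eig"]

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one, tiny negatives clipped to zero."""
        if t < 0:
            raise ParameterError(f"branch length must be non-negative, got {t}")
        if self._use_expm:
            from scipy.linalg import expm

            P = expm(self.Q * t)
        else:
            lam, right, left = self._eigendecompose()
            P = (right * np.exp(lam * self._factor * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        rowsum = P.sum(axis=1, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        return P / rowsum

    def transition_batch(self, ts: np.ndarray) -> np.ndarray:
        """Stack of P(t) for many branch lengths at once: (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ParameterError("branch lengths must be non-negative")
        if self._use_expm:
            return np.stack([self.transition(t) for t in ts])
        lam, right, left = self._eigendecompose()
        expvals = np.exp(np.outer(ts * self._factor, lam))   # (m, n)
        P = (right[None, :, :] * expvals[:, None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        rowsum = P.sum(axis=2, keepdims=True)
        rowsum[rowsum == 0] = 1.0
        P /= rowsum
        return P


def build_rate_matrix(
    kappa: float,
    omega: float,
    pi: CodonFrequencies,
    code: GeneticCode | None = None,
    scale: bool = True,
) -> RateMatrix:
    """Construct a Goldman–Yang rate matrix (see :class:`RateMatrix`)."""
    return RateMatrix(kappa, omega, pi, code=code, scale=scale)


def transition_matrix(Q: RateMatrix, t: float) -> np.ndarray:
    """Codon transition probabilities over branch length ``t``."""
    return Q.transition(t)
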