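"""Felsenstein-pruning likelihoods for site-class mixture codon models.

Site models treat the nonsynonymous/synonymous ratio omega as a random
effect over sites: each site belongs to one of a small number of omega
classes, and the per-site likelihood is a weighted sum over classes.
Branch-site and two-ratio variants additionally let a class's omega differ
between tagged foreground branches and the background.

The engine computes, for every alignment site and every class, the pruning
likelihood conditional on the class (in log space, with per-node scaling),
from which mixture log-likelihoods and empirical-Bayes posteriors follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .codons import MISSING, CodonAlignment, CodonFrequencies, RateMatrix

__all__ = [
    "SiteClass",
    "MixtureEngine",
    "ClassSiteLikelihoods",
    "class_site_likelihoods",
    "mixture_log_likelihood",
    "TaxonMismatchError",
]


class TaxonMismatchError(ValueError):
    """Tree leaves are not a subset of the alignment's taxa."""


@dataclass(frozen=True)
class SiteClass:
    """One omega class: mixture weight plus background/foreground ratios."""

    weight: float
    omega: float                 # background omega
    omega_fore: float | None = None   # differs only in branch-site/two-ratio models

    @property
    def fore(self) -> float:
        return self.omega if self.omega_fore is None else self.omega_fore


class MixtureEngine:
    """Per-class transition-matrix provider for a site-class mixture.

    Builds one (background, foreground) rate-matrix pair per class, all
    rescaled by a single mixture-weighted factor so that one unit of branch
    length equals one expected substitution per codon under the background
    mixture — branch lengths then keep the same meaning across models.
    """

    def __init__(
        self,
        kappa: float,
        classes: list[SiteClass],
        pi: CodonFrequencies,
        code=None,
        scaling: str = "mixture",
        eig_cache: dict | None = None,
    ) -> None:
        if not classes:
            raise ValueError("at least one site class required")
        w = np.array([c.weight for c in classes], dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("class weights must be non-negative and sum to 1")
        self.classes = classes
        self.kappa = float(kappa)
        self.pi = pi
        self.weights = w / w.sum()
        back = [
            RateMatrix(kappa, c.omega, pi, code=code, scale=False, eig_cache=eig_cache)
            for c in classes
        ]
        fore = [
            b if c.omega_fore is None
            else RateMatrix(kappa, c.fore, pi, code=code, scale=False, eig_cache=eig_cache)
            for b, c in zip(back, classes)
        ]
        if scaling == "mixture":
            rho = float(sum(wk * m.unscaled_rate for wk, m in zip(self.weights, back)))
        elif scaling == "per-class":
            rho = None
        else:
            raise ValueError(f"unknown scaling {scaling!r}")
        for m in set(back) | set(fore):
            m.rescale(rho if rho is not None and rho > 0 else max(m.unscaled_rate, 1e-300))
        self.background = back
        self.foreground = fore

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def class_omegas(self) -> np.ndarray:
        return np.array([c.omega for c in self.classes])

    def matrices(self, k: int) -> tuple[RateMatrix, RateMatrix]:
        return self.background[k], self.foreground[k]


@dataclass
class ClassSiteLikelihoods:
    """Per-site log-likelihoods conditional on each omega class."""

    logL: np.ndarray            # (n_sites, n_classes)
    class_omegas: np.ndarray
    class_weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.class_weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("class weights must be non-negative and sum to 1")

    @property
    def n_sites(self) -> int:
        return int(self.logL.shape[0])

    @property
    def n_classes(self) -> int:
        return int(self.logL.shape[1])


def _compress_patterns(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (taxa x patterns) and site -> pattern index."""
    patterns, inverse = np.unique(states, axis=1, return_inverse=True)
    return patterns, inverse.ravel()


def _class_pattern_loglik(
    patterns: np.ndarray,
    tree,
    back: RateMatrix,
    fore: RateMatrix,
    pi: np.ndarray,
) -> np.ndarray:
    """Pruning over unique patterns for a single omega class."""
    n_states = pi.size
    n_pat = patterns.shape[1]
    leaf_row = {node: row for row, node in enumerate(_tree_leaf_order(tree))}
    # all branch transition matrices for this class in two batched calls
    nonroot = [v for v in tree.postorder if v != tree.root]
    P_of: dict[int, np.ndarray] = {}
    fg = [v for v in nonroot if tree.foreground[v]]
    bg = [v for v in nonroot if not tree.foreground[v]]
    if bg:
        for v, P in zip(bg, back.transition_batch(tree.lengths[bg])):
            P_of[v] = P
    if fg:
        for v, P in zip(fg, fore.transition_batch(tree.lengths[fg])):
            P_of[v] = P
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_pat)
    for node in tree.postorder:
        if not tree.children[node]:
            continue
        F = np.ones((n_states, n_pat))
        for child in tree.children[node]:
            P = P_of[child]
            if not tree.children[child]:
                patt = patterns[leaf_row[child]]
                obs = patt >= 0
                if obs.all():
                    contrib = P[:, patt]
                else:
                    contrib = np.ones((n_states, n_pat))
                    if obs.any():
                        contrib[:, obs] = P[:, patt[obs]]
            else:
                contrib = P @ partial.pop(child)
            F *= contrib
        mx = F.max(axis=0)
        safe = mx > 0
        F[:, safe] /= mx[safe]
        with np.errstate(divide="ignore"):
            logscale += np.where(safe, np.log(np.where(safe, mx, 1.0)), -np.inf)
        partial[node] = F
    root_partial = partial.get(tree.root)
    if root_partial is None:  # single-leaf tree
        patt = patterns[leaf_row[tree.root]]
        obs = patt >= 0
        root_partial = np.ones((n_states, n_pat))
        root_partial[:, obs] = np.eye(n_states)[:, patt[obs]]
    site_like = pi @ root_partial
    with np.errstate(divide="ignore"):
        return np.log(site_like) + logscale


def _tree_leaf_order(tree) -> list[int]:
    return tree.leaves


def class_site_likelihoods(
    aln: CodonAlignment, tree, engine: MixtureEngine
) -> ClassSiteLikelihoods:
    """Per-site, per-class pruning log-likelihoods.

    MISSING states are marginalized (partial vector of ones); computation
    uses per-node scaling so deep trees and long branches do not underflow.
    """
    missing = set(tree.leaf_labels) - set(aln.taxa)
    if missing:
        raise TaxonMismatchError(
            f"tree leaves absent from alignment: {sorted(missing)}"
        )
    rows = [aln.taxa.index(tree.labels[node]) for node in tree.leaves]
    states = aln.states[rows]
    if aln.n_sites == 0:
        return ClassSiteLikelihoods(
            np.zeros((0, engine.n_classes)), engine.class_omegas, engine.weights
        )
    patterns, inverse = _compress_patterns(states)
    pi = np.asarray(engine.pi.pi, float)
    logL = np.empty((aln.n_sites, engine.n_classes))
    for k in range(engine.n_classes):
        back, fore = engine.matrices(k)
        per_pattern = _class_pattern_loglik(patterns, tree, back, fore, pi)
        logL[:, k] = per_pattern[inverse]
    return ClassSiteLikelihoods(logL, engine.class_omegas, engine.weights)


def mixture_log_likelihood(csl: ClassSiteLikelihoods) -> float:
    """Total log-likelihood: sum over sites of log sum_k p_k L_k(site)."""
    if csl.n_sites == 0:
        warnings.warn("empty alignment: log-likelihood is 0")
        return 0.0
    with np.errstate(divide="ignore"):
        logw = np.where(csl.class_weights > 0, np.log(
            np.where(csl.class_weights > 0, csl.class_weights, 1.0)), -np.inf)
    per_site = logsumexp(csl.logL + logw[None, :], axis=1)
    return float(per_site.sum())
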