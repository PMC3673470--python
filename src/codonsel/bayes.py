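"""Per-site empirical-Bayes posteriors over omega classes.

NEB (naive empirical Bayes) plugs the maximum-likelihood estimates in and
applies Bayes' rule per site.  The BEB grid variant additionally averages
over uncertainty in the M8-family mixture parameters ``(p0, omega_s)`` on
a uniform grid, weighting grid points by their marginal likelihood — a
documented approximation of the full Bayes empirical Bayes calculation in
the reference codon-model software (which also integrates over more
parameters and uses fixed priors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .likelihood import ClassSiteLikelihoods

__all__ = ["SitePosteriors", "site_class_posteriors"]

#: Grid resolution per mixture parameter for the BEB average.
BEB_GRID_POINTS = 11
#: omega_s grid spans (1, OMEGA_S_GRID_MAX); bin midpoints are used.
OMEGA_S_GRID_MAX = 11.0


@dataclass
class SitePosteriors:
    """Posterior probability of each omega class at each site."""

    PP: np.ndarray               # (n_sites, n_classes), rows sum to 1
    class_omegas: np.ndarray
    method: str                  # "NEB" | "BEB_grid"

    def __post_init__(self) -> None:
        self.PP = np.asarray(self.PP, float)
        self.class_omegas = np.asarray(self.class_omegas, float)
        if self.PP.ndim != 2 or self.PP.shape[1] != self.class_omegas.size:
            raise ValueError("PP shape does not match class count")
        if self.PP.size:
            if np.any(self.PP < -1e-12) or np.any(self.PP > 1 + 1e-12):
                raise ValueError("posterior probabilities outside [0,1]")
            rowsum = self.PP.sum(axis=1)
            if np.any(np.abs(rowsum - 1.0) > 1e-9):
                raise ValueError("posterior rows must sum to 1")

    @property
    def n_sites(self) -> int:
        return int(self.PP.shape[0])

    @property
    def n_classes(self) -> int:
        return int(self.PP.shape[1])


def _neb_pp(csl: ClassSiteLikelihoods) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logw = np.where(
            csl.class_weights > 0,
            np.log(np.where(csl.class_weights > 0, csl.class_weights, 1.0)),
            -np.inf,
        )
    joint = csl.logL + logw[None, :]
    return np.exp(joint - logsumexp(joint, axis=1, keepdims=True))


def site_class_posteriors(
    fit, csl: ClassSiteLikelihoods, method: str = "NEB"
) -> SitePosteriors:
    """Posterior omega-class probabilities per site for a fitted model.

    ``method="NEB"`` conditions on the MLE; ``"BEB_grid"`` (alias
    ``"BEB"``) averages over an 11x11 uniform grid on ``(p0, omega_s)``
    for the M8 variant (p0 only for M8a), falling back to NEB with a
    warning for variants outside the M8 family.  In the BEB result the
    positive class's reported omega is its grid-posterior mean.
    """
    if fit is not None and csl.n_classes != len(fit.spec.site_classes()):
        raise ValueError("class count of site likelihoods does not match the fitted model")
    if method in ("NEB", "neb"):
        return SitePosteriors(_neb_pp(csl), csl.class_omegas, "NEB")
    if method not in ("BEB", "BEB_grid", "beb"):
        raise ValueError(f"unknown posterior method {method!r}")
    if fit is None:
        raise ValueError("the BEB grid needs the fitted model")
    if fit.variant not in ("M8", "M8a"):
        warnings.warn(
            f"BEB grid is defined for the M8 family; using NEB for {fit.variant}"
        )
        return SitePosteriors(_neb_pp(csl), csl.class_omegas, "NEB")

    g = BEB_GRID_POINTS
    mid = (2.0 * np.arange(1, g + 1) - 1.0) / (2.0 * g)
    p0_grid = mid
    if fit.variant == "M8":
        ws_grid = 1.0 + (OMEGA_S_GRID_MAX - 1.0) * mid
    else:
        ws_grid = np.array([1.0])

    n_sites = csl.n_sites
    n_classes = csl.n_classes
    K = n_classes - 1
    pp_sum = np.zeros((n_sites, n_classes))
    ws_sum = 0.0
    log_marg = []
    pieces = []
    for ws in ws_grid:
        spec_ws = replace(fit.spec, omega_s=float(ws))
        csl_ws = fit.model.class_site_likelihoods(spec_ws, fit.branch_lengths)
        for p0 in p0_grid:
            w = np.concatenate([np.full(K, p0 / K), [1.0 - p0]])
            joint = csl_ws.logL + np.log(w)[None, :]
            per_site = logsumexp(joint, axis=1)
            log_marg.append(per_site.sum())
            pieces.append((joint, per_site, ws))
    log_marg = np.array(log_marg)
    grid_post = np.exp(log_marg - logsumexp(log_marg))
    for wgt, (joint, per_site, ws) in zip(grid_post, pieces):
        pp_sum += wgt * np.exp(joint - per_site[:, None])
        ws_sum += wgt * ws
    pp_sum /= pp_sum.sum(axis=1, keepdims=True)
    class_omegas = csl.class_omegas.copy()
    class_omegas[-1] = ws_sum
    return SitePosteriors(pp_sum, class_omegas, "BEB_grid")
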