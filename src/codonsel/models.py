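"""Codon selection models and maximum-likelihood fitting.

The model zoo covers the classic site-model hierarchy and the lineage
tests built on it:

``M0``
    one omega shared by all sites and branches;
``M7``
    omega varies over sites following a Beta(p, q) on (0, 1), discretized
    into K equal-probability categories;
``M8``
    M7 plus an extra site class with proportion ``p_s = 1 - p0`` and ratio
    ``omega_s >= 1`` (the positive-selection class);
``M8a``
    M8 with ``omega_s`` fixed at 1 (the boundary null for the M8 test);
``BranchSiteA`` / ``BranchSiteA_null``
    the revised branch-site model A: four site classes in which
    ``omega_2 > 1`` (fixed to 1 in the null) applies only on tagged
    foreground branches;
``TwoRatio``
    one omega on foreground branches, another on the background, constant
    across sites (tested against M0).

Fitting follows the statsmodels idiom: construct a :class:`CodonModel`
from data, call :meth:`CodonModel.fit`, and work with the returned
:class:`CodonModelResults` (log-likelihood, estimates, ``summary()``,
``site_posteriors()``, ``lrt()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import betainc, expit, logit
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .codons import (
    AlignmentInputError,
    CodonAlignment,
    CodonFrequencies,
    ParameterError,
    codon_frequencies,
)
from .likelihood import (
    ClassSiteLikelihoods,
    MixtureEngine,
    SiteClass,
    TaxonMismatchError,
    _class_pattern_loglik,
    _compress_patterns,
)
from .trees import PhyloTree

__all__ = [
    "OmegaModel",
    "CodonModel",
    "CodonModelResults",
    "FitOptions",
    "LRTResult",
    "discretize_beta",
    "embed_null",
    "fit",
    "lrt",
    "LRT_DF",
    "SITE_VARIANTS",
    "BRANCH_VARIANTS",
]

SITE_VARIANTS = ("M0", "M7", "M8", "M8a")
BRANCH_VARIANTS = ("BranchSiteA", "BranchSiteA_null", "TwoRatio")
VARIANTS = SITE_VARIANTS + BRANCH_VARIANTS

#: Degrees of freedom of the supported nested likelihood-ratio tests,
#: keyed by (null variant, alternative variant).  The M8-vs-M8a contrast
#: uses one degree of freedom.
LRT_DF = {
    ("M7", "M8"): 2,
    ("M8a", "M8"): 1,
    ("BranchSiteA_null", "BranchSiteA"): 1,
    ("M0", "TwoRatio"): 1,
}


def discretize_beta(p: float, q: float, K: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Discretize Beta(p, q) into K equal-probability omega categories.

    Each category's omega is the conditional mean of the distribution over
    its bin, computed from the incomplete beta function; weights are all
    1/K.  Means are strictly increasing inside (0, 1).
    """
    if p <= 0 or q <= 0:
        raise ParameterError(f"beta shapes must be positive, got p={p}, q={q}")
    if K < 2:
        raise ParameterError(f"need at least 2 categories, got K={K}")
    u = np.linspace(0.0, 1.0, K + 1)
    edges = beta_dist.ppf(u, p, q)
    # E[X | bin] = (p/(p+q)) * (I(hi; p+1, q) - I(lo; p+1, q)) * K.  For
    # bins in the upper tail the incomplete-beta difference underflows, so
    # there we use the mirror distribution: with Y = 1 - X ~ Beta(q, p),
    # E[X | bin] = 1 - E[Y | mirrored bin], on tail coordinates obtained
    # directly from the survival quantile (never via 1 - edge).
    mirror_edges = beta_dist.isf(u, q, p)          # = 1 - edges, accurately
    direct = (p / (p + q)) * np.diff(betainc(p + 1.0, q, edges)) * K
    tail = betainc(q + 1.0, p, mirror_edges)
    mirror = 1.0 - (q / (p + q)) * (tail[:-1] - tail[1:]) * K
    means = np.where(edges[:-1] > 0.5, mirror, direct)
    means = np.clip(means, 1e-300, 1.0 - 1e-16)
    return means, np.full(K, 1.0 / K)


@dataclass(frozen=True)
class OmegaModel:
    """A model specification (variant plus its parameter values).

    Only the fields relevant to ``variant`` are meaningful; the rest keep
    their defaults.  ``p_s`` (the positive-class proportion of M8/M8a) is
    derived as ``1 - p0``.
    """

    variant: str = "M8"
    kappa: float = 2.0
    omega: float = 0.4           # M0 / both ratios' seed value
    beta_p: float = 1.0
    beta_q: float = 2.0
    p0: float = 0.9              # beta-component proportion (M8/M8a); class-0 prop (branch-site)
    p1: float = 0.05             # branch-site class-1 proportion
    omega_s: float = 2.0         # extra-class omega (M8; fixed 1 in M8a)
    omega0: float = 0.2          # branch-site purifying omega (< 1)
    omega2: float = 2.0          # branch-site foreground omega (>= 1; fixed 1 in null)
    omega_fore: float = 0.4      # two-ratio foreground omega
    omega_back: float = 0.4      # two-ratio background omega
    K: int = 10

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown model variant {self.variant!r}")
        if self.K < 2:
            raise ParameterError("K must be >= 2")
        if self.kappa <= 0:
            raise ParameterError("kappa must be positive")
        for name in ("omega", "omega_s", "omega0", "omega2", "omega_fore", "omega_back"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not (0.0 <= self.p0 <= 1.0 and 0.0 <= self.p1 <= 1.0):
            raise ParameterError("class proportions must lie in [0,1]")
        if self.variant in ("BranchSiteA", "BranchSiteA_null") and self.p0 + self.p1 > 1.0 + 1e-12:
            raise ParameterError("branch-site proportions p0 + p1 must not exceed 1")
        if self.variant == "M8" and self.omega_s < 1.0:
            raise ParameterError("M8 constrains omega_s >= 1")
        if self.variant == "M8a":
            object.__setattr__(self, "omega_s", 1.0)
        if self.variant == "BranchSiteA_null":
            object.__setattr__(self, "omega2", 1.0)

    @property
    def p_s(self) -> float:
        """Proportion of the extra (potentially positive) class."""
        return 1.0 - self.p0

    def site_classes(self) -> list[SiteClass]:
        """The mixture's (weight, background omega, foreground omega) classes."""
        v = self.variant
        if v == "M0":
            return [SiteClass(1.0, self.omega)]
        if v == "TwoRatio":
            return [SiteClass(1.0, self.omega_back, self.omega_fore)]
        if v == "M7":
            means, w = discretize_beta(self.beta_p, self.beta_q, self.K)
            return [SiteClass(wk, om) for wk, om in zip(w, means)]
        if v in ("M8", "M8a"):
            means, w = discretize_beta(self.beta_p, self.beta_q, self.K)
            cls = [SiteClass(self.p0 * wk, om) for wk, om in zip(w, means)]
            cls.append(SiteClass(1.0 - self.p0, self.omega_s))
            return cls
        # revised branch-site model A: classes 0, 1, 2a, 2b
        p2 = max(1.0 - self.p0 - self.p1, 0.0)
        denom = max(self.p0 + self.p1, 1e-12)
        p2a = p2 * self.p0 / denom
        p2b = p2 * self.p1 / denom
        return [
            SiteClass(self.p0, self.omega0, self.omega0),
            SiteClass(self.p1, 1.0, 1.0),
            SiteClass(p2a, self.omega0, self.omega2),
            SiteClass(p2b, 1.0, self.omega2),
        ]

    @property
    def n_free_params(self) -> int:
        """Free model parameters (kappa included, branch lengths excluded)."""
        return {
            "M0": 2, "M7": 3, "M8": 5, "M8a": 4,
            "BranchSiteA": 5, "BranchSiteA_null": 4, "TwoRatio": 3,
        }[self.variant]

    @property
    def uses_foreground(self) -> bool:
        return self.variant in BRANCH_VARIANTS


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :meth:`CodonModel.fit`.

    ``branch_mode``:
        ``"fixed"`` — use the input tree's branch lengths as-is;
        ``"m0"``    — estimate branch lengths jointly under M0 first, then
                      freeze them for the target model (fast default);
        ``"joint"`` — optimize branch lengths jointly with the target
                      model's parameters, warm-started from the M0 fit.
    """

    n_starts: int = 3
    seed: int = 0
    branch_mode: str = "m0"
    maxiter: int = 500
    ftol: float = 1e-11
    eps: float = 1e-6


@dataclass
class LRTResult:
    """A likelihood-ratio test: statistic, degrees of freedom, raw p-value."""

    test_name: str
    stat: float
    df: int
    p_raw: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ParameterError("df must be >= 1")
        self.stat = max(0.0, float(self.stat))
        if not (0.0 <= self.p_raw <= 1.0):
            raise ParameterError("p-value outside [0,1]")


# ---------------------------------------------------------------------------
# parameter packing: free parameters live in an unconstrained space
# (log for rates, logit for proportions, log(x-1) for omegas bounded below by 1)

_LOW, _HIGH = -15.0, 15.0


def _pack_spec(spec: OmegaModel) -> tuple[np.ndarray, list[str]]:
    names: list[str] = ["kappa"]
    x = [np.log(spec.kappa)]

    def add(name: str, value: float) -> None:
        names.append(name)
        x.append(value)

    v = spec.variant
    if v == "M0":
        add("omega", np.log(max(spec.omega, 1e-8)))
    elif v in ("M7", "M8", "M8a"):
        add("beta_p", np.log(spec.beta_p))
        add("beta_q", np.log(spec.beta_q))
        if v in ("M8", "M8a"):
            add("p0", logit(np.clip(spec.p0, 1e-9, 1 - 1e-9)))
        if v == "M8":
            add("omega_s", np.log(max(spec.omega_s - 1.0, 1e-7)))
    elif v in ("BranchSiteA", "BranchSiteA_null"):
        s = np.clip(spec.p0 + spec.p1, 1e-9, 1 - 1e-9)
        add("p01_sum", logit(s))
        add("p0_frac", logit(np.clip(spec.p0 / s, 1e-9, 1 - 1e-9)))
        add("omega0", logit(np.clip(spec.omega0, 1e-9, 1 - 1e-9)))
        if v == "BranchSiteA":
            add("omega2", np.log(max(spec.omega2 - 1.0, 1e-7)))
    elif v == "TwoRatio":
        add("omega_back", np.log(max(spec.omega_back, 1e-8)))
        add("omega_fore", np.log(max(spec.omega_fore, 1e-8)))
    return np.array(x), names


def _unpack_spec(x: np.ndarray, names: list[str], template: OmegaModel) -> OmegaModel:
    vals = dict(zip(names, x))
    kw: dict[str, float] = {"kappa": float(np.exp(vals["kappa"]))}
    v = template.variant
    if v == "M0":
        kw["omega"] = float(np.exp(vals["omega"]))
    elif v in ("M7", "M8", "M8a"):
        kw["beta_p"] = float(np.exp(vals["beta_p"]))
        kw["beta_q"] = float(np.exp(vals["beta_q"]))
        if v in ("M8", "M8a"):
            kw["p0"] = float(expit(vals["p0"]))
        if v == "M8":
            kw["omega_s"] = float(1.0 + np.exp(vals["omega_s"]))
    elif v in ("BranchSiteA", "BranchSiteA_null"):
        s = float(expit(vals["p01_sum"]))
        f = float(expit(vals["p0_frac"]))
        kw["p0"] = s * f
        kw["p1"] = s * (1.0 - f)
        kw["omega0"] = float(expit(vals["omega0"]))
        if v == "BranchSiteA":
            kw["omega2"] = float(1.0 + np.exp(vals["omega2"]))
    elif v == "TwoRatio":
        kw["omega_back"] = float(np.exp(vals["omega_back"]))
        kw["omega_fore"] = float(np.exp(vals["omega_fore"]))
    return replace(template, **kw)


class CodonModel:
    """A codon selection model bound to an alignment and a tree.

    Parameters
    ----------
    alignment
        In-frame codon alignment; taxa must cover the tree's leaves.
    tree
        Phylogeny with branch lengths (and foreground tags for the
        branch-site / two-ratio variants).
    variant
        One of ``M0, M7, M8, M8a, BranchSiteA, BranchSiteA_null, TwoRatio``.
    ncat
        Beta discretization categories for the M7/M8-family variants.
    freq
        Equilibrium-frequency estimator (``F3x4`` default, or ``uniform``,
        ``F1x4``, ``F61``); ignored when ``pi`` is given explicitly.
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree,
        variant: str = "M8",
        *,
        ncat: int = 10,
        freq: str = "F3x4",
        pi: CodonFrequencies | None = None,
        scaling: str = "mixture",
    ) -> None:
        if variant not in VARIANTS:
            raise ParameterError(f"unknown model variant {variant!r}")
        if alignment.n_sites == 0:
            raise AlignmentInputError("cannot model an alignment with zero codon sites")
        missing = set(tree.leaf_labels) - set(alignment.taxa)
        if missing:
            raise TaxonMismatchError(f"tree leaves absent from alignment: {sorted(missing)}")
        if variant in BRANCH_VARIANTS and not tree.has_foreground:
            raise ParameterError(
                f"{variant} requires at least one foreground-tagged branch"
            )
        self.alignment = alignment
        self.tree = tree
        self.variant = variant
        self.ncat = int(ncat)
        self.scaling = scaling
        self.pi = pi if pi is not None else codon_frequencies(alignment, freq)
        rows = [alignment.taxa.index(tree.labels[node]) for node in tree.leaves]
        patterns, inverse = _compress_patterns(alignment.states[rows])
        self._patterns = patterns
        self._counts = np.bincount(inverse, minlength=patterns.shape[1]).astype(float)
        self._pi_vec = np.asarray(self.pi.pi, float)
        self._eig_cache: dict = {}

    # -- likelihood -----------------------------------------------------

    def _pattern_class_loglik(
        self, spec: OmegaModel, lengths: np.ndarray | None = None
    ) -> tuple[np.ndarray, MixtureEngine]:
        tree = self.tree if lengths is None else self.tree.with_lengths(lengths)
        engine = MixtureEngine(
            spec.kappa, spec.site_classes(), self.pi, code=self.alignment.code,
            scaling=self.scaling, eig_cache=self._eig_cache,
        )
        n_pat = self._patterns.shape[1]
        logL = np.empty((n_pat, engine.n_classes))
        for k in range(engine.n_classes):
            back, fore = engine.matrices(k)
            logL[:, k] = _class_pattern_loglik(self._patterns, tree, back, fore, self._pi_vec)
        return logL, engine

    def loglike(self, spec: OmegaModel, lengths: np.ndarray | None = None) -> float:
        """Mixture log-likelihood of the data under ``spec``."""
        logL, engine = self._pattern_class_loglik(spec, lengths)
        with np.errstate(divide="ignore"):
            logw = np.where(engine.weights > 0,
                            np.log(np.where(engine.weights > 0, engine.weights, 1.0)),
                            -np.inf)
        shifted = logL + logw[None, :]
        mx = shifted.max(axis=1)
        per_pattern = mx + np.log(np.exp(shifted - mx[:, None]).sum(axis=1))
        return float((per_pattern * self._counts).sum())

    def class_site_likelihoods(
        self, spec: OmegaModel, lengths: np.ndarray | None = None
    ) -> ClassSiteLikelihoods:
        """Per-site per-class log-likelihoods at the given parameter values."""
        tree = self.tree if lengths is None else self.tree.with_lengths(lengths)
        from .likelihood import class_site_likelihoods as _csl

        engine = MixtureEngine(
            spec.kappa, spec.site_classes(), self.pi, code=self.alignment.code,
            scaling=self.scaling,
        )
        return _csl(self.alignment, tree, engine)

    # -- fitting --------------------------------------------------------

    def _default_starts(self, n_starts: int, rng: np.random.Generator) -> list[OmegaModel]:
        base = OmegaModel(variant=self.variant, K=self.ncat)
        starts = [base]
        # a second deterministic start near the null end of the parameter
        # space guards the nesting inequalities around the omega = 1 boundary
        if self.variant == "M8":
            starts.append(replace(base, p0=0.98, omega_s=1.0 + 1e-6, beta_p=0.5, beta_q=1.5))
        elif self.variant == "M8a":
            starts.append(replace(base, p0=0.98, beta_p=0.5, beta_q=1.5))
        elif self.variant == "M7":
            starts.append(replace(base, beta_p=0.5, beta_q=1.5))
        elif self.variant == "BranchSiteA":
            starts.append(replace(base, omega2=1.0 + 1e-6, p0=0.7, p1=0.25))
        elif self.variant == "TwoRatio":
            starts.append(replace(base, omega_back=0.2, omega_fore=0.2))
        elif self.variant == "M0":
            starts.append(replace(base, omega=0.1, kappa=4.0))
        while len(starts) < n_starts:
            x0, names = _pack_spec(base)
            x = np.clip(x0 + rng.normal(0.0, 0.7, size=x0.size), _LOW, _HIGH)
            starts.append(_unpack_spec(x, names, base))
        return starts[:n_starts]

    def fit(
        self,
        opts: FitOptions | None = None,
        *,
        start: OmegaModel | None = None,
        branch_lengths: np.ndarray | None = None,
        m0_result: "CodonModelResults | None" = None,
        extra_starts: "list[OmegaModel] | None" = None,
        **kwargs,
    ) -> "CodonModelResults":
        """Maximize the log-likelihood; deterministic given ``opts.seed``.

        ``branch_lengths`` overrides the tree's lengths and implies
        ``branch_mode="fixed"``; ``m0_result`` supplies a pre-computed M0
        fit whose branch lengths are reused under ``branch_mode="m0"``
        (or warm-start the ``"joint"`` mode).  ``extra_starts`` adds warm
        starts on top of the default multi-start schedule — typically the
        nested null's MLE embedded via :func:`embed_null`, which makes the
        nesting inequality lnL(alt) >= lnL(null) structural rather than a
        hope about optimizer paths.
        """
        if opts is None:
            opts = FitOptions(**kwargs)
        elif kwargs:
            opts = replace(opts, **kwargs)
        mode = opts.branch_mode
        if branch_lengths is not None:
            mode = "fixed"
        if mode not in ("fixed", "m0", "joint"):
            raise ParameterError(f"unknown branch_mode {mode!r}")

        fixed_lengths = branch_lengths
        if mode == "fixed" and fixed_lengths is None:
            fixed_lengths = np.asarray(self.tree.lengths, float)
        if mode in ("m0", "joint") and self.variant != "M0":
            if m0_result is None:
                m0 = CodonModel(
                    self.alignment, self.tree, "M0",
                    pi=self.pi, scaling=self.scaling,
                )
                m0_result = m0.fit(replace(opts, branch_mode="joint", n_starts=1))
            fixed_lengths = m0_result.branch_lengths
        joint = mode == "joint" or (mode == "m0" and self.variant == "M0")
        if joint and fixed_lengths is None:
            fixed_lengths = np.clip(self.tree.lengths, 1e-4, None)
            fixed_lengths[self.tree.root] = 0.0

        rng = np.random.default_rng(opts.seed)
        starts = self._default_starts(opts.n_starts, rng)
        if start is not None:
            starts = [replace(start, variant=self.variant, K=self.ncat)] + starts[: max(opts.n_starts - 1, 0)]
        for s in extra_starts or []:
            if s.variant != self.variant:
                raise ParameterError(
                    f"extra start variant {s.variant!r} != model variant {self.variant!r}"
                )
            starts.append(replace(s, K=self.ncat))

        nonroot = [i for i in range(self.tree.n_nodes) if i != self.tree.root]

        def objective(z: np.ndarray, names: list[str], template: OmegaModel) -> float:
            spec = _unpack_spec(z[: len(names)], names, template)
            if joint:
                lens = np.zeros(self.tree.n_nodes)
                lens[nonroot] = np.exp(z[len(names):])
            else:
                lens = fixed_lengths
            try:
                ll = self.loglike(spec, lens)
            except (FloatingPointError, np.linalg.LinAlgError):
                return 1e12
            if not np.isfinite(ll):
                return 1e12
            return -ll

        best = None
        any_converged = False
        for s in starts:
            x0, names = _pack_spec(s)
            if joint:
                t0 = np.clip(fixed_lengths[nonroot], 1e-6, None)
                x0 = np.concatenate([x0, np.log(t0)])
            bounds = [(_LOW, _HIGH)] * len(names) + ([(-16.0, 5.0)] * (len(x0) - len(names)))
            res = optimize.minimize(
                objective, x0, args=(names, s), method="L-BFGS-B", bounds=bounds,
                options={"maxiter": opts.maxiter, "ftol": opts.ftol, "eps": opts.eps,
                         "maxfun": 10 * opts.maxiter * len(x0)},
            )
            if not res.success:
                # line searches can abort on finite-difference noise; polish
                # from the incumbent with a finer step before giving up
                polish = optimize.minimize(
                    objective, res.x, args=(names, s), method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": opts.maxiter, "ftol": opts.ftol,
                             "eps": min(opts.eps, 1e-8),
                             "maxfun": 10 * opts.maxiter * len(x0)},
                )
                if polish.fun <= res.fun:
                    res = polish
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best[0].fun:
                best = (res, names, s)

        res, names, template = best
        mle = _unpack_spec(res.x[: len(names)], names, template)
        if joint:
            lens = np.zeros(self.tree.n_nodes)
            lens[nonroot] = np.exp(res.x[len(names):])
        else:
            lens = np.asarray(fixed_lengths, float)
        llf = -float(res.fun)
        if not any_converged:
            warnings.warn(f"{self.variant} fit did not converge after {opts.n_starts} start(s)")
        return CodonModelResults(
            model=self,
            spec=mle,
            llf=llf,
            branch_lengths=lens,
            branch_mode=mode,
            converged=any_converged,
            n_starts=opts.n_starts,
            seed=opts.seed,
        )


@dataclass
class CodonModelResults:
    """A fitted codon model: estimates, log-likelihood and derived output."""

    model: CodonModel
    spec: OmegaModel
    llf: float
    branch_lengths: np.ndarray
    branch_mode: str
    converged: bool
    n_starts: int
    seed: int
    _csl: ClassSiteLikelihoods | None = field(default=None, repr=False)

    @property
    def variant(self) -> str:
        return self.spec.variant

    @property
    def n_free_params(self) -> int:
        return self.spec.n_free_params

    @property
    def params(self) -> dict[str, float]:
        """The variant's free parameter estimates by name."""
        s = self.spec
        v = s.variant
        out = {"kappa": s.kappa}
        if v == "M0":
            out["omega"] = s.omega
        elif v in ("M7", "M8", "M8a"):
            out.update(beta_p=s.beta_p, beta_q=s.beta_q)
            if v in ("M8", "M8a"):
                out.update(p0=s.p0, p_s=s.p_s, omega_s=s.omega_s)
        elif v in ("BranchSiteA", "BranchSiteA_null"):
            out.update(p0=s.p0, p1=s.p1, omega0=s.omega0, omega2=s.omega2)
        elif v == "TwoRatio":
            out.update(omega_back=s.omega_back, omega_fore=s.omega_fore)
        return out

    def class_site_likelihoods(self) -> ClassSiteLikelihoods:
        """Per-site, per-class log-likelihoods at the MLE (cached)."""
        if self._csl is None:
            self._csl = self.model.class_site_likelihoods(self.spec, self.branch_lengths)
        return self._csl

    def site_posteriors(self, method: str = "BEB"):
        """Per-site posterior omega-class probabilities (NEB or BEB grid)."""
        from .bayes import site_class_posteriors

        return site_class_posteriors(self, self.class_site_likelihoods(), method=method)

    def lrt(self, null: "CodonModelResults", test_name: str | None = None) -> LRTResult:
        """Likelihood-ratio test of this (alternative) fit against ``null``."""
        return lrt(null, self, test_name=test_name)

    def mean_omega(self) -> float:
        """Mixture-mean dN/dS (prior-weighted over site classes)."""
        classes = self.spec.site_classes()
        return float(sum(c.weight * c.omega for c in classes))

    def summary(self) -> str:
        s = self.spec
        lines = [
            f"Codon selection model {s.variant}",
            "=" * 34,
            f"  taxa / codon sites : {self.model.alignment.n_taxa} / {self.model.alignment.n_sites}",
            f"  log-likelihood     : {self.llf:.4f}",
            f"  free parameters    : {self.n_free_params} (+ branch lengths: {self.branch_mode})",
            f"  converged          : {self.converged}  (starts={self.n_starts}, seed={self.seed})",
            "  estimates:",
        ]
        for k, v in self.params.items():
            lines.append(f"    {k:10s} = {v:.6g}")
        lines.append(f"    tree length = {float(self.branch_lengths.sum()):.4f}")
        return "\n".join(lines)


def embed_null(null_spec: OmegaModel, alt_variant: str) -> OmegaModel:
    """Express a fitted null model inside its alternative's parameter space.

    The embedded point sits a hair inside the alternative's boundary (e.g.
    ``omega_s = 1 + 1e-7`` for M8a inside M8) so it is a feasible warm
    start whose log-likelihood matches the null's up to that epsilon.
    """
    pair = (null_spec.variant, alt_variant)
    eps = 1e-7
    if pair == ("M7", "M8"):
        return replace(null_spec, variant="M8", p0=1.0 - eps, omega_s=1.0 + eps)
    if pair == ("M8a", "M8"):
        return replace(null_spec, variant="M8", omega_s=1.0 + eps)
    if pair == ("BranchSiteA_null", "BranchSiteA"):
        return replace(null_spec, variant="BranchSiteA", omega2=1.0 + eps)
    if pair == ("M0", "TwoRatio"):
        return replace(
            null_spec, variant="TwoRatio",
            omega_back=null_spec.omega, omega_fore=null_spec.omega,
        )
    raise ParameterError(f"no nesting embedding for {pair}")


def fit(
    aln: CodonAlignment,
    tree: PhyloTree,
    model: OmegaModel,
    opts: FitOptions | None = None,
    **kwargs,
) -> CodonModelResults:
    """Functional wrapper: fit ``model.variant`` to (alignment, tree)."""
    cm = CodonModel(aln, tree, model.variant, ncat=model.K)
    return cm.fit(opts, start=model, **kwargs)


def lrt(
    null_fit: CodonModelResults,
    alt_fit: CodonModelResults,
    test_name: str | None = None,
    df: int | None = None,
    boundary: str = "chi2",
) -> LRTResult:
    """Likelihood-ratio test between a nested null and alternative fit.

    The statistic ``2 (lnL_alt - lnL_null)`` is clipped at zero and referred
    to a chi-square with degrees of freedom determined by the variant pair
    (M7 vs M8: 2; M8a vs M8: 1; branch-site null vs alternative: 1; M0 vs
    two-ratio: 1).

    ``boundary="chi2"`` (default) uses the plain chi-square reference even
    for boundary nulls such as M8a inside M8, which is conservative.
    ``boundary="mixture"`` instead uses the 50:50 mixture of a point mass
    at zero and chi-square(df) appropriate when the null pins one
    parameter to the boundary of the alternative's space; this option is
    provided for sensitivity analysis and is not what the default
    reporting uses.
    """
    pair = (null_fit.variant, alt_fit.variant)
    if df is None:
        if pair not in LRT_DF:
            raise ParameterError(
                f"{pair[0]} is not a supported null for {pair[1]}; "
                f"supported pairs: {sorted(LRT_DF)}"
            )
        df = LRT_DF[pair]
    stat = max(0.0, 2.0 * (alt_fit.llf - null_fit.llf))
    if boundary == "chi2":
        p_raw = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    elif boundary == "mixture":
        p_raw = float(0.5 * chi2.sf(stat, df)) if stat > 0 else 1.0
    else:
        raise ParameterError(f"unknown boundary handling {boundary!r}")
    name = test_name or f"{pair[0]}_vs_{pair[1]}"
    return LRTResult(test_name=name, stat=stat, df=df, p_raw=p_raw)
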