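# Methods

## Substitution model

All inference rests on a Goldman–Yang codon process on the 61 sense
codons of the standard genetic code (codons ordered lexicographically
over T, C, A, G; stop codons are excluded from the state space and
rejected in input). Off-diagonal rates are

    q_ij = 0                        if codons i, j differ at > 1 position
    q_ij = pi_j                     synonymous transversion
    q_ij = kappa * pi_j             synonymous transition
    q_ij = omega * pi_j             nonsynonymous transversion
    q_ij = kappa * omega * pi_j     nonsynonymous transition

with κ > 0 the transition/transversion rate ratio and ω ≥ 0 the
nonsynonymous/synonymous (dN/dS) ratio. Equilibrium frequencies π come
from the alignment: `F3x4` (position-specific nucleotide frequencies,
renormalized over sense codons) is the default, with `uniform`, `F1x4`
and `F61` (pseudocount 0.5 per codon) selectable. The documentation of
the codeml-family tools does not pin the frequency model used in any
particular published run, so F3x4 is a default, not a reproduction
guarantee.

**Scaling.** In a mixture model every class matrix is divided by the same
mixture-weighted expected rate ρ = Σₖ pₖ · (−Σᵢ πᵢ q⁽ᵏ⁾ᵢᵢ), so that one
unit of branch length is one expected substitution per codon under the
background mixture, and branch lengths keep the same meaning across
model variants. A standalone matrix built by `build_rate_matrix` is
scaled to unit rate by itself.

**Matrix exponential.** The reversible Q is similar to a symmetric matrix
via diag(√π); P(t) = exp(Qt) is computed from the eigendecomposition of
that symmetrization, with all branch lengths of a class handled in one
batched product. Decompositions of the unscaled Q are cached per
(κ, ω) within a model object, which makes finite-difference gradients
cheap: perturbing a proportion parameter re-uses every cached class.
When π contains exact zeros (degenerate alignments) the code falls back
to `scipy.linalg.expm`. Entries are clipped at zero and rows
renormalized; deviations are at the 1e-12 level and are asserted in the
test suite at the 1e-8..1e-10 tolerances the checks state.

## Likelihood

Per-site likelihoods conditional on each ω class are computed by
Felsenstein pruning over unique site patterns, in linear space with
per-node rescaling (running log accumulators), so alignments with ≥1000
taxa and arbitrary branch lengths do not underflow. A triplet containing
a gap or non-ACGT character is treated as MISSING and marginalized (its
partial vector is all ones); this is the whole treatment of alignment
ambiguity — the package does not reproduce manual curation of
alignment-ambiguous regions. Unrooted/multifurcating Newick inputs are
accepted as parsed; correctness under arbitrary rooting follows from
reversibility and is covered by a pulley-principle test. Branch lengths
missing from a Newick default to 0.1 with a warning.

## Model variants and fitting

Variants: M0, M7 (beta-distributed ω with K = 10 equal-probability
categories by default), M8 (beta + positive class, ω_s ≥ 1), M8a
(ω_s = 1), revised branch-site model A (classes 0, 1, 2a, 2b with
proportions p0, p1 and the 2a/2b split proportional to p0 : p1; ω₂ ≥ 1 on
foreground branches, fixed to 1 in the null) and the two-ratio branch
model. The M8 implementation constrains ω_s ≥ 1 throughout; published
codeml tables sometimes show M8 fits with ω_s below or at 1, which that
tool's unconstrained variant permits — here such fits simply end on the
boundary ω_s = 1.

Beta categories are the conditional means of K equal-mass bins, computed
from the regularized incomplete beta function; bins in the upper tail use
the mirror distribution Beta(q, p) on survival-quantile coordinates, a
numerically necessary step for extreme shapes (p or q ≪ 1) where naive
differencing destroys monotonicity. A quadrature oracle checks the bin
means to 1e-6.

Maximization is bounded L-BFGS-B on transformed parameters (log for κ, ω
and branch lengths; logit for proportions; log(x−1) for ratios bounded
below by 1), with multi-start (deterministic defaults plus seeded random
perturbations; identical seed ⇒ identical result). Convergence uses a
relative function tolerance of 1e-11 with finite-difference step 1e-6; a
failed line search triggers one polish pass at step 1e-8. Branch
lengths are fitted jointly under M0 and then frozen for the other
variants (`branch_mode="m0"`, the default); a fully joint mode and a
fixed-length mode exist. Freezing at the M0 estimates trades a small
amount of likelihood for a large amount of time and applies the same
lengths to both members of every test pair.

**Nesting by construction.** Every alternative fit accepts extra warm
starts; the pipeline always passes the null's MLE embedded just inside
the alternative's boundary (e.g. ω_s = 1 + 1e-7). Since L-BFGS-B only
improves on its start, lnL(alt) ≥ lnL(null) holds up to that epsilon and
LRT statistics cannot go negative except by ~1e-7 (they are clipped at
zero regardless).

## Tests and multiple-testing correction

LRT degrees of freedom follow the variant pair: M7 vs M8 → 2, M8 vs M8a
→ 1, branch-site A vs its null → 1, two-ratio vs M0 → 1. The M8-vs-M8a
and branch-site nulls sit on the boundary of the alternative's parameter
space; the package uses the plain χ²₁ reference distribution for them by
default, which is conservative — the null-calibration suite measures the
actual rejection rate. `lrt(..., boundary="mixture")` switches to the
50:50 χ²₀:χ²₁ mixture reference for sensitivity analysis; default
reporting does not use it.

Tests are grouped into hypothesis families declared in the study
manifest; families may overlap (the same test can be corrected within
two different families, receiving a family-specific adjusted value in
each). Correction is Benjamini–Hochberg step-up by default, delegated to
`statsmodels.stats.multitest` behind the `bh_fdr` surface and verified
in tests against a brute-force step-up implementation; Holm step-down is
available because at least one published family's corrected values follow
the step-down arithmetic even though the text calls every correction the
same FDR procedure. The package defaults to BH and leaves the choice in
the manifest.

## Empirical-Bayes posteriors

NEB plugs the MLE in: PPₖ(s) = pₖ Lₖ(s) / Σⱼ pⱼ Lⱼ(s). The BEB grid
(default for reporting) averages the same quantity over an 11 × 11
uniform grid on (p0, ω_s) for M8 — 11 points on p0 only for M8a — with
grid points weighted by their marginal likelihood, all other parameters
held at the MLE. This is a deliberate, documented approximation of the
full Bayes-empirical-Bayes calculation (which integrates more parameters
under fixed priors); the positive class's reported ω is its grid-
posterior mean. The ω_s grid spans (1, 11) on bin midpoints. For
variants outside the M8 family the BEB request falls back to NEB with a
warning. Posterior standard errors are out of scope.

Posteriors (and everything downstream) are computed from the M8 fit for
every data set, whether or not the M7-vs-M8 LRT is significant;
significance is carried as a separate flag and positive-selection claims
are made only where the LRT supports them.

## Conservation index and DAM mapping

Per site: ω̄ = Σₖ PPₖ ωₖ; CI = 1 − ω̄ if ω̄ < 1 else 0 (neutral and
positively selected sites get CI 0 by definition, making CI a pure
purifying-selection scale). The minimum-ω category accumulates PP from
the lowest ω class and reports the first class whose cumulative PP
exceeds 0.95 (the top class if none does); category ω < 0.25 flags
significant purifying selection. Thresholds (0.95, 0.25, and the CI 0.9
used in DAM summaries) live in the manifest.

Codon sites, alignment columns and protein positions are all 1-based;
site ↔ amino acid is one-to-one. A DAM at protein position p maps to the
p-th alignment column at which the designated reference taxon has an
observed codon — i.e. reference gaps (and ambiguous reference codons,
which are indistinguishable from gaps after masking) shift the mapping.
How published DAM coordinates were reconciled against gapped or
isoform-shifted references is not specified anywhere authoritative; this
gap-offset rule is the package's documented choice. A mismatch between
the table's reference amino acid and the translated reference codon is
flagged but not fatal; positions beyond the reference's ungapped length
are skipped with a logged error. External classifier scores (e.g.
PolyPhen-2 values) are a pass-through column only.

## Synthetic data

The generator is the forward counterpart of the inference models: i.i.d.
site classes from the mixture weights (no autocorrelation of ω along the
sequence — matching the inference model's assumption, not biological
realism), root codons from π, evolution by the class- and
branch-appropriate transition matrices. Missing data, when requested, is
masked in an exact count of uniformly chosen cells. Trees are random
pairwise-join topologies with Exponential(0.15) branch lengths unless
supplied. Synthetic DAM tables draw positions with a configurable
enrichment weight toward sites whose true class is the lowest-ω class
(weight 1 forces all DAMs onto such sites), mirroring the expectation
that disease mutations concentrate at conserved sites.

What the simulator does **not** emulate: indels and alignment error,
among-site rate autocorrelation, selection on synonymous codon usage,
convergent substitution between lineages, and base-composition
heterogeneity across the tree. Passing tests therefore demonstrate
correctness of the inference machinery under its own assumptions, not
robustness to real-data violations of them.

## Study conditions and problem sizes

The standard synthetic study uses 12-taxon trees, 300-codon genes, an M8
generator with a strongly purifying beta component (p = 0.2, q = 1.5,
mean ω̄_beta ≈ 0.12), a 10% positive class at ω_s = 2, and DAM tables of
10 positions per gene at enrichment 0.9 — sample sizes and effect sizes
in the range of real single-gene alignments of this kind. Calibration
and power suites use 8 taxa × 200 codons × 50 replicates (null,
M8a-simulated) and 16 taxa × 500 codons (M8-simulated) with a handful of
seeds for the recovery median; replicate counts are chosen so the full
suite completes in minutes-scale time on a single core, and every
reported rate states its n.

## Known limitations

- Numerical gradients only; very flat ridges (e.g. beta shapes under
  weak information) can end with `converged=False` — the flag is
  reported honestly and such fits are still returned.
- The BEB grid approximation can differ from reference-implementation
  BEB probabilities in the second decimal for weakly informed sites.
- χ²₁ at boundary nulls is conservative; measured type-I error is
  typically 2–5% at nominal 5%.
- The branch-site and two-ratio models assume the foreground tagging is
  given; no search over foreground placements is performed.
- No codon-frequency estimation under F61 maximum likelihood; empirical
  counts with a pseudocount only.
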