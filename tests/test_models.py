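"""Model specifications, beta discretization, fitting and LRTs."""

from types import SimpleNamespace

import numpy as np
import pytest

import codonsel as cs
from codonsel.codons import AlignmentInputError, ParameterError
from codonsel.models import (
    CodonModel,
    FitOptions,
    OmegaModel,
    discretize_beta,
    embed_null,
    lrt,
)
from oracles import beta_bin_means_quadrature

UNIFORM = cs.codon_frequencies(None, "uniform")


class TestDiscretizeBeta:
    def test_uniform_two_bins(self):
        means, weights = discretize_beta(1.0, 1.0, 2)
        np.testing.assert_allclose(means, [0.25, 0.75], atol=1e-12)
        np.testing.assert_allclose(weights, [0.5, 0.5])

    def test_overall_mean_matches_beta_expectation(self):
        means, _ = discretize_beta(0.2, 1.5, 10)
        assert means.mean() == pytest.approx(0.2 / 1.7, abs=1e-6)

    @pytest.mark.parametrize("p,q,K", [(0.2, 1.5, 10), (2.0, 3.0, 5), (0.5, 0.5, 8)])
    def test_bin_means_match_quadrature_oracle(self, p, q, K):
        means, _ = discretize_beta(p, q, K)
        expect = beta_bin_means_quadrature(p, q, K)
        np.testing.assert_allclose(means, expect, atol=1e-6)

    @pytest.mark.parametrize("p,q", [(0.7, 4.0), (0.05, 0.05), (6.0, 0.08)])
    def test_means_strictly_increasing_in_unit_interval(self, p, q):
        # extreme shapes push bin masses into the tails, where naive
        # incomplete-beta differencing loses monotonicity
        means, _ = discretize_beta(p, q, 10)
        assert np.all(np.diff(means) > 0)
        assert means.min() > 0 and means.max() < 1

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ParameterError):
            discretize_beta(0.0, 1.0, 10)
        with pytest.raises(ParameterError):
            discretize_beta(1.0, 1.0, 1)


class TestOmegaModel:
    def test_m8_constrains_omega_s(self):
        with pytest.raises(ParameterError):
            OmegaModel(variant="M8", omega_s=0.5)

    def test_m8a_and_branch_site_null_fix_boundaries(self):
        assert OmegaModel(variant="M8a", omega_s=3.0).omega_s == 1.0
        assert OmegaModel(variant="BranchSiteA_null", omega2=5.0).omega2 == 1.0

    def test_class_weights_sum_to_one(self):
        for variant in ("M0", "M7", "M8", "M8a", "BranchSiteA", "TwoRatio"):
            spec = OmegaModel(variant=variant)
            total = sum(c.weight for c in spec.site_classes())
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_free_parameter_counts(self):
        expected = {"M0": 2, "M7": 3, "M8": 5, "M8a": 4,
                    "BranchSiteA": 5, "BranchSiteA_null": 4, "TwoRatio": 3}
        for variant, n in expected.items():
            assert OmegaModel(variant=variant).n_free_params == n


class TestLRT:
    def _res(self, variant, llf):
        return SimpleNamespace(variant=variant, llf=llf)

    def test_equal_likelihoods_give_stat_zero_p_one(self):
        r = lrt(self._res("M8a", -100.0), self._res("M8", -100.0))
        assert r.stat == 0.0
        assert r.p_raw == 1.0

    def test_chi2_quantile_at_five_percent(self):
        r = lrt(self._res("M8a", 0.0), self._res("M8", 3.841459 / 2.0))
        assert r.p_raw == pytest.approx(0.05, abs=1e-4)
        assert r.df == 1

    def test_df_follows_variant_pair(self):
        assert lrt(self._res("M7", -10.0), self._res("M8", -9.0)).df == 2
        assert lrt(self._res("M8a", -10.0), self._res("M8", -9.0)).df == 1
        assert lrt(self._res("BranchSiteA_null", -10.0), self._res("BranchSiteA", -9.0)).df == 1
        assert lrt(self._res("M0", -10.0), self._res("TwoRatio", -9.0)).df == 1

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ParameterError):
            lrt(self._res("M7", -10.0), self._res("TwoRatio", -9.0))

    def test_negative_excursions_clipped_at_zero(self):
        r = lrt(self._res("M8a", -99.9), self._res("M8", -100.0))
        assert r.stat == 0.0


class TestFit:
    def test_identical_sequences_drive_branches_to_zero(self):
        rng = np.random.default_rng(0)
        states = np.tile(rng.integers(0, 61, size=30), (3, 1))
        aln = cs.CodonAlignment(["A", "B", "C"], states.astype(np.int32), cs.standard_code())
        tree = cs.read_newick("(A:0.05,B:0.05,C:0.05);")
        res = CodonModel(aln, tree, "M0", pi=UNIFORM).fit(
            FitOptions(n_starts=1, seed=0, branch_mode="joint")
        )
        expect = np.log(UNIFORM.pi[states[0]]).sum()
        assert res.llf == pytest.approx(expect, abs=1e-3)
        assert res.branch_lengths.sum() < 1e-4

    def test_m0_omega_recovery_matches_grid_search_oracle(self, small_m0_data):
        aln, tree, truth, model = small_m0_data
        cm = CodonModel(aln, tree, "M0", pi=UNIFORM)
        res = cm.fit(FitOptions(n_starts=1, seed=0, branch_mode="fixed"))
        assert 0.15 <= res.params["omega"] <= 0.25
        # independent grid search over omega at the generating kappa
        grid = np.arange(0.05, 0.55, 0.01)
        lls = [
            cm.loglike(OmegaModel(variant="M0", omega=w, kappa=res.params["kappa"]))
            for w in grid
        ]
        best = grid[int(np.argmax(lls))]
        assert abs(best - res.params["omega"]) <= 0.011
        assert max(lls) <= res.llf + 1e-6

    def test_fit_is_deterministic_given_seed(self, small_m0_data):
        aln, tree, _, _ = small_m0_data
        opts = FitOptions(n_starts=2, seed=7, branch_mode="fixed")
        r1 = CodonModel(aln, tree, "M0").fit(opts)
        r2 = CodonModel(aln, tree, "M0").fit(opts)
        assert r1.llf == r2.llf
        assert r1.params == r2.params

    def test_zero_site_alignment_rejected(self):
        aln = cs.CodonAlignment(["A", "B"], np.zeros((2, 0), np.int32), cs.standard_code())
        tree = cs.read_newick("(A:0.1,B:0.1);")
        with pytest.raises(AlignmentInputError):
            CodonModel(aln, tree, "M0")

    def test_branch_models_require_foreground_tags(self, small_m0_data):
        aln, tree, _, _ = small_m0_data
        with pytest.raises(ParameterError, match="foreground"):
            CodonModel(aln, tree, "TwoRatio")

    def test_summary_reports_variant_and_loglik(self, small_m0_data):
        aln, tree, _, _ = small_m0_data
        res = CodonModel(aln, tree, "M0").fit(
            FitOptions(n_starts=1, seed=0, branch_mode="fixed")
        )
        text = res.summary()
        assert "M0" in text and f"{res.llf:.4f}" in text


class TestEmbedNull:
    @pytest.mark.parametrize(
        "null_variant,alt_variant",
        [("M7", "M8"), ("M8a", "M8"), ("BranchSiteA_null", "BranchSiteA"),
         ("M0", "TwoRatio")],
    )
    def test_embedded_null_matches_null_likelihood(self, null_variant, alt_variant):
        tree = cs.read_newick("((A:0.2,B:0.3)#1:0.1,C:0.4);")
        model = cs.OmegaModel(variant="M0", omega=0.3)
        aln, _ = cs.simulate_alignment(tree, model, 40, seed=21)
        cm_null = CodonModel(aln, tree, null_variant, pi=UNIFORM)
        cm_alt = CodonModel(aln, tree, alt_variant, pi=UNIFORM)
        spec = OmegaModel(variant=null_variant)
        embedded = embed_null(spec, alt_variant)
        assert cm_alt.loglike(embedded) == pytest.approx(
            cm_null.loglike(spec), abs=1e-4
        )

    def test_unknown_pair_rejected(self):
        with pytest.raises(ParameterError):
            embed_null(OmegaModel(variant="M7"), "TwoRatio")


class TestBoundaryMixture:
    def _res(self, variant, llf):
        return SimpleNamespace(variant=variant, llf=llf)

    def test_mixture_reference_halves_positive_tail(self):
        null, alt = self._res("M8a", 0.0), self._res("M8", 3.841459 / 2.0)
        plain = lrt(null, alt)
        mixed = lrt(null, alt, boundary="mixture")
        assert mixed.p_raw == pytest.approx(plain.p_raw / 2.0, rel=1e-12)

    def test_mixture_at_zero_statistic_is_one(self):
        r = lrt(self._res("M8a", -5.0), self._res("M8", -5.0), boundary="mixture")
        assert r.p_raw == 1.0
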