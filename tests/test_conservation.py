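"""Conservation index, minimum-omega categories and DAM mapping."""

import logging

import numpy as np
import pandas as pd
import pytest

import codonsel as cs
from codonsel.bayes import SitePosteriors
from codonsel.conservation import (
    ConservationProfile,
    DAMRecord,
    conservation_index,
    conservation_profile,
    dam_overlap_summary,
    map_dams,
    min_omega_category,
    read_dam_table,
    weighted_mean_omega,
)

CODE = cs.standard_code()


def _post(PP, omegas):
    return SitePosteriors(np.atleast_2d(PP), np.asarray(omegas, float), "NEB")


class TestWeightedMeanOmega:
    def test_degenerate_posterior(self):
        post = _post([[1.0, 0.0]], [0.1, 1.5])
        assert weighted_mean_omega(post)[0] == pytest.approx(0.1)

    def test_hand_arithmetic(self):
        post = _post([[0.5, 0.5]], [0.1, 1.5])
        assert weighted_mean_omega(post)[0] == pytest.approx(0.8)

    def test_convex_combination_bounds(self, rng):
        PP = rng.dirichlet(np.ones(4), size=20)
        omegas = np.array([0.0, 0.3, 1.0, 2.5])
        ob = weighted_mean_omega(_post(PP, omegas))
        assert np.all(ob >= omegas.min() - 1e-12)
        assert np.all(ob <= omegas.max() + 1e-12)


class TestConservationIndex:
    def test_strong_purifying_site(self):
        assert conservation_index(np.array([0.1]))[0] == pytest.approx(0.9)

    def test_positively_selected_site_set_to_zero(self):
        # a site with weighted-mean omega 1.476 is neutral-or-positive: CI 0
        assert conservation_index(np.array([1.476]))[0] == 0.0

    def test_boundaries(self):
        np.testing.assert_allclose(conservation_index(np.array([1.0, 0.0])), [0.0, 1.0])

    def test_negative_omega_bar_rejected(self):
        with pytest.raises(ValueError):
            conservation_index(np.array([-0.1]))

    def test_ci_equals_clamped_complement_sitewise(self, rng):
        ob = rng.uniform(0, 2, size=200)
        np.testing.assert_array_equal(
            conservation_index(ob), np.maximum(0.0, 1.0 - ob)
        )


class TestMinOmegaCategory:
    def test_concentrated_lowest_class(self):
        idx, val, sig = min_omega_category(_post([[1.0, 0.0, 0.0]], [0.05, 0.3, 1.2]))
        assert idx[0] == 0 and val[0] == pytest.approx(0.05) and sig[0]

    def test_cumulative_sum_crosses_in_second_class(self):
        idx, val, sig = min_omega_category(_post([[0.60, 0.36, 0.04]], [0.0, 0.2, 1.3]))
        assert idx[0] == 1 and val[0] == pytest.approx(0.2) and sig[0]

    def test_mass_in_top_class_is_not_purifying(self):
        idx, val, sig = min_omega_category(_post([[0.10, 0.10, 0.80]], [0.0, 0.2, 1.5]))
        assert idx[0] == 2 and val[0] == pytest.approx(1.5) and not sig[0]

    def test_unordered_classes_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            min_omega_category(_post([[0.5, 0.5]], [1.0, 0.2]))

    def test_monotone_under_mass_shift_to_lower_classes(self, rng):
        omegas = [0.0, 0.2, 0.6, 1.5]
        for _ in range(50):
            PP = rng.dirichlet(np.ones(4))
            idx0, _, _ = min_omega_category(_post([PP], omegas))
            hi = int(rng.integers(1, 4))
            lo = int(rng.integers(0, hi))
            delta = PP[hi] * rng.uniform()
            shifted = PP.copy()
            shifted[hi] -= delta
            shifted[lo] += delta
            idx1, _, _ = min_omega_category(_post([shifted], omegas))
            assert idx1[0] <= idx0[0]


def _profile_for(aln, ci):
    n = aln.n_sites
    from codonsel.conservation import _reference_positions

    return ConservationProfile(
        omega_bar=1.0 - np.asarray(ci),
        ci=np.asarray(ci, float),
        min_omega_class=np.zeros(n, dtype=int),
        min_omega_value=np.full(n, 0.1),
        significant_purifying=np.asarray(ci) > 0.5,
        reference_position=_reference_positions(aln),
        gene="g",
        reference_name=aln.reference_name,
    )


def _dam_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene", "protein_position", "ref_aa", "alt_aa",
                       "source_id", "external_score"]
    )


class TestMapDams:
    def _aln(self, ref_seq, other_seq):
        text = f">ref\n{ref_seq}\n>other\n{other_seq}\n"
        return cs.read_codon_alignment(text, reference_name="ref")

    def test_ungapped_reference_is_identity_mapping(self):
        aln = self._aln("ATGAAACCTGGTTGGATT", "ATGAAACCTGGTTGGATT")
        prof = _profile_for(aln, [0.9, 0.8, 0.95, 0.2, 0.99, 1.0])
        dams = _dam_frame([["g", 5, "W", "R", "v1", None]])
        mapped = map_dams(dams, aln, prof)
        assert mapped.loc[0, "mapped_column"] == 5
        assert mapped.loc[0, "mapped_ci"] == pytest.approx(0.99)
        assert bool(mapped.loc[0, "ref_aa_match"])

    def test_reference_gap_shifts_mapping(self):
        # reference gapped at column 3: protein position 5 -> column 6
        aln = self._aln("ATGAAA---GGTTGGATT", "ATGAAACCTGGTTGGATT")
        prof = _profile_for(aln, [0.9, 0.8, 0.95, 0.2, 0.99, 0.7])
        mapped = map_dams(_dam_frame([["g", 5, "I", "V", "v1", None]]), aln, prof)
        assert mapped.loc[0, "mapped_column"] == 6
        assert mapped.loc[0, "mapped_ci"] == pytest.approx(0.7)

    def test_out_of_range_position_skipped_and_logged(self, caplog):
        aln = self._aln("ATGAAACCT", "ATGAAACCT")
        prof = _profile_for(aln, [0.9, 0.8, 0.95])
        with caplog.at_level(logging.ERROR):
            mapped = map_dams(_dam_frame([["g", 10, "A", "T", "v1", None]]), aln, prof)
        assert len(mapped) == 0
        assert "exceeds reference length" in caplog.text

    def test_ref_aa_mismatch_flagged_not_dropped(self, caplog):
        aln = self._aln("ATGAAACCT", "ATGAAACCT")
        prof = _profile_for(aln, [0.9, 0.8, 0.95])
        with caplog.at_level(logging.WARNING):
            mapped = map_dams(_dam_frame([["g", 2, "Q", "R", "v1", None]]), aln, prof)
        assert len(mapped) == 1
        assert not bool(mapped.loc[0, "ref_aa_match"])


class TestOverlapSummary:
    def test_hand_counts(self):
        mapped = pd.DataFrame(
            {"gene": ["g"] * 5, "mapped_ci": [0.95, 0.99, 0.20, 0.91, 0.85]}
        )
        summary = dam_overlap_summary(mapped, ci_threshold=0.9)
        overall = summary[summary.gene == "ALL"].iloc[0]
        assert overall.n_dams == 5 and overall.n_ci_at_or_above == 3

    def test_all_fully_conserved(self):
        mapped = pd.DataFrame({"gene": ["a", "b"], "mapped_ci": [1.0, 1.0]})
        summary = dam_overlap_summary(mapped)
        assert (summary.n_ci_below == 0).all()

    def test_empty_table_gives_zero_counts(self):
        summary = dam_overlap_summary(pd.DataFrame(columns=["gene", "mapped_ci"]))
        assert summary.iloc[0].n_dams == 0


class TestProfileAndRecords:
    def test_profile_frame_uses_one_based_coordinates_with_na_gaps(self):
        aln = cs.read_codon_alignment(
            ">ref\nATG---AAA\n>o\nATGCCTAAA\n", reference_name="ref"
        )
        post = _post(np.tile([0.7, 0.3], (3, 1)), [0.1, 1.2])
        prof = conservation_profile(post, aln, gene="g")
        frame = prof.to_frame()
        assert list(frame.alignment_column) == [1, 2, 3]
        assert list(frame.reference_position.astype("object")) == [1, pd.NA, 2]

    def test_profile_invariants(self):
        post = _post(np.tile([0.2, 0.8], (4, 1)), [0.1, 1.4])
        prof = conservation_profile(post)
        np.testing.assert_array_equal(prof.ci, np.maximum(0, 1 - prof.omega_bar))
        assert np.all(prof.significant_purifying == (prof.min_omega_value < 0.25))

    def test_dam_record_validation(self):
        with pytest.raises(ValueError, match="missense"):
            DAMRecord("g", 3, "A", "A")
        with pytest.raises(ValueError, match="1-based"):
            DAMRecord("g", 0, "A", "T")

    def test_read_dam_table_fills_optional_columns(self):
        text = "gene\tprotein_position\tref_aa\talt_aa\ng\t4\tA\tT\n"
        df = read_dam_table(text)
        assert list(df.columns)[:4] == ["gene", "protein_position", "ref_aa", "alt_aa"]
        assert df.loc[0, "protein_position"] == 4
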