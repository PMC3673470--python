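"""Pruning likelihoods: oracle equivalence and structural invariants."""

import numpy as np
import pytest

import codonsel as cs
from codonsel.likelihood import (
    MixtureEngine,
    SiteClass,
    TaxonMismatchError,
    class_site_likelihoods,
    mixture_log_likelihood,
)
from oracles import brute_force_site_likelihood

CODE = cs.standard_code()
UNIFORM = cs.codon_frequencies(None, "uniform")


def _aln_from_states(labels, states):
    return cs.CodonAlignment(labels, np.asarray(states, np.int32), CODE)


def _engine(kappa=2.0, omegas=(0.5,), weights=None, fore=None):
    if weights is None:
        weights = [1.0 / len(omegas)] * len(omegas)
    classes = [
        SiteClass(w, om, None if fore is None else fore[i])
        for i, (w, om) in enumerate(zip(weights, omegas))
    ]
    return MixtureEngine(kappa, classes, UNIFORM)


def test_star_tree_zero_lengths_gives_pi():
    tree = cs.read_newick("(A:0.0,B:0.0,C:0.0);")
    state = CODE.index("ATG")
    aln = _aln_from_states(["A", "B", "C"], [[state]] * 3)
    csl = class_site_likelihoods(aln, tree, _engine())
    assert np.exp(csl.logL[0, 0]) == pytest.approx(1.0 / 61, rel=1e-12)


def test_all_missing_column_has_log_likelihood_zero():
    tree = cs.read_newick("(A:0.1,B:0.2);")
    aln = _aln_from_states(["A", "B"], [[cs.MISSING], [cs.MISSING]])
    csl = class_site_likelihoods(aln, tree, _engine())
    assert csl.logL[0, 0] == pytest.approx(0.0, abs=1e-12)


def test_taxon_mismatch_names_offenders():
    tree = cs.read_newick("(A:0.1,X:0.2);")
    aln = _aln_from_states(["A", "B"], [[0], [1]])
    with pytest.raises(TaxonMismatchError, match="X"):
        class_site_likelihoods(aln, tree, _engine())


def _oracle_check(tree, aln, engine, rel=1e-12):
    """Compare pruning against exhaustive ancestral-state enumeration."""
    csl = class_site_likelihoods(aln, tree, engine)
    leaf_of = {v: aln.taxa.index(tree.labels[v]) for v in tree.leaves}
    for k in range(engine.n_classes):
        back, fore = engine.matrices(k)
        P_of = {
            v: (fore if tree.foreground[v] else back).transition(tree.lengths[v])
            for v in range(tree.n_nodes) if v != tree.root
        }
        for s in range(aln.n_sites):
            leaf_states = {v: int(aln.states[leaf_of[v], s]) for v in tree.leaves}
            expect = brute_force_site_likelihood(tree, leaf_states, P_of, UNIFORM.pi)
            got = np.exp(csl.logL[s, k])
            assert got == pytest.approx(expect, rel=rel)


@pytest.mark.parametrize(
    "newick",
    [
        "(A:0.2,B:0.4,C:0.1);",
        "((A:0.15,B:0.3):0.2,C:0.5);",
        "((A:0.1,B:0.1):0.05,(C:0.3,D:0.2):0.4);",
    ],
)
def test_pruning_equals_enumeration_small_trees(newick):
    tree = cs.read_newick(newick)
    rng = np.random.default_rng(7)
    n_leaves = len(tree.leaves)
    states = rng.integers(0, 61, size=(n_leaves, 3))
    states[0, 2] = cs.MISSING  # one missing cell exercises marginalization
    aln = _aln_from_states(sorted(tree.leaf_labels), states)
    _oracle_check(tree, aln, _engine(kappa=1.8, omegas=(0.2, 1.5), weights=(0.7, 0.3)))


def test_pruning_equals_enumeration_with_foreground_branch():
    tree = cs.read_newick("((A:0.1,B:0.1)#1:0.05,C:0.3);")
    rng = np.random.default_rng(3)
    aln = _aln_from_states(["A", "B", "C"], rng.integers(0, 61, size=(3, 4)))
    engine = _engine(omegas=(0.3,), fore=(2.0,))
    _oracle_check(tree, aln, engine)


def test_likelihood_invariant_to_rerooting():
    # the same unrooted 4-taxon tree, rooted on two different branches
    t1 = cs.read_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.07);")
    t2 = cs.read_newick("(A:0.1,B:0.2,(C:0.3,D:0.4):0.12);")
    rng = np.random.default_rng(11)
    aln = _aln_from_states(["A", "B", "C", "D"], rng.integers(0, 61, size=(4, 20)))
    eng = _engine(omegas=(0.4, 1.2), weights=(0.6, 0.4))
    ll1 = mixture_log_likelihood(class_site_likelihoods(aln, t1, eng))
    ll2 = mixture_log_likelihood(class_site_likelihoods(aln, t2, eng))
    assert ll1 == pytest.approx(ll2, abs=1e-10)


def test_all_missing_taxon_does_not_change_likelihood():
    t1 = cs.read_newick("((A:0.1,B:0.2):0.05,C:0.3);")
    t2 = cs.read_newick("(((A:0.1,E:0.7):0.0,B:0.2):0.05,C:0.3);")
    rng = np.random.default_rng(13)
    base = rng.integers(0, 61, size=(3, 15))
    aln1 = _aln_from_states(["A", "B", "C"], base)
    aln2 = _aln_from_states(
        ["A", "B", "C", "E"],
        np.vstack([base, np.full((1, 15), cs.MISSING)]),
    )
    eng = _engine(omegas=(0.5,))
    ll1 = mixture_log_likelihood(class_site_likelihoods(aln1, t1, eng))
    ll2 = mixture_log_likelihood(class_site_likelihoods(aln2, t2, eng))
    assert ll1 == pytest.approx(ll2, abs=1e-10)


def test_deep_tree_long_branches_do_not_underflow(rng):
    tree = cs.random_tree(64, seed=2, mean_branch=1.5)
    model = cs.OmegaModel(variant="M0", omega=0.5)
    aln, _ = cs.simulate_alignment(tree, model, 30, seed=4)
    csl = class_site_likelihoods(aln, tree, _engine(omegas=(0.5,)))
    assert np.all(np.isfinite(csl.logL))


class TestMixtureLogLikelihood:
    def test_single_class_equals_summed_class_loglik(self):
        tree = cs.read_newick("(A:0.1,B:0.2);")
        rng = np.random.default_rng(1)
        aln = _aln_from_states(["A", "B"], rng.integers(0, 61, size=(2, 10)))
        csl = class_site_likelihoods(aln, tree, _engine(omegas=(0.5,)))
        assert mixture_log_likelihood(csl) == pytest.approx(csl.logL.sum(), rel=1e-12)

    def test_two_identical_classes_match_single_class(self):
        tree = cs.read_newick("(A:0.1,B:0.2);")
        rng = np.random.default_rng(1)
        aln = _aln_from_states(["A", "B"], rng.integers(0, 61, size=(2, 10)))
        one = mixture_log_likelihood(class_site_likelihoods(aln, tree, _engine(omegas=(0.5,))))
        two = mixture_log_likelihood(
            class_site_likelihoods(aln, tree, _engine(omegas=(0.5, 0.5), weights=(0.5, 0.5)))
        )
        assert two == pytest.approx(one, rel=1e-12)

    def test_site_order_invariance(self):
        tree = cs.read_newick("(A:0.1,B:0.2,C:0.15);")
        rng = np.random.default_rng(8)
        states = rng.integers(0, 61, size=(3, 25))
        eng = _engine(omegas=(0.1, 1.0), weights=(0.5, 0.5))
        ll = mixture_log_likelihood(
            class_site_likelihoods(_aln_from_states(["A", "B", "C"], states), tree, eng)
        )
        perm = rng.permutation(25)
        ll_perm = mixture_log_likelihood(
            class_site_likelihoods(_aln_from_states(["A", "B", "C"], states[:, perm]), tree, eng)
        )
        assert ll == pytest.approx(ll_perm, rel=1e-12)

    def test_empty_alignment_warns_and_returns_zero(self):
        tree = cs.read_newick("(A:0.1,B:0.2);")
        aln = _aln_from_states(["A", "B"], np.zeros((2, 0)))
        csl = class_site_likelihoods(aln, tree, _engine())
        with pytest.warns(UserWarning, match="empty"):
            assert mixture_log_likelihood(csl) == 0.0
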