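"""Independent oracles used by the test suite.

Each oracle implements the *definition* of a quantity by brute force —
exhaustive enumeration, numerical quadrature, or the step-up rejection
rule — deliberately avoiding the package's own algorithms so the two
routes can disagree.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.stats import beta as beta_dist


def brute_force_site_likelihood(tree, leaf_states: dict[int, int], P_of, pi) -> float:
    """Likelihood of one site by summing over ALL ancestral-state assignments.

    ``leaf_states`` maps leaf node id -> observed codon state (or -1 for
    missing, whose factor is dropped, i.e. marginalized).  ``P_of`` maps a
    node id to the transition matrix on the branch above it.  Exponential
    in the number of internal nodes; only usable on tiny trees.
    """
    n_states = pi.size
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    leaves = [v for v in range(tree.n_nodes) if not tree.children[v]]
    total = 0.0
    for assignment in itertools.product(range(n_states), repeat=len(internal)):
        state = dict(zip(internal, assignment))
        for v in leaves:
            state[v] = leaf_states[v]
        prob = pi[state[tree.root]]
        for v in range(tree.n_nodes):
            if v == tree.root:
                continue
            if state[v] < 0:       # missing leaf: marginalized, factor sums to 1
                continue
            prob *= P_of[v][state[tree.parent[v]], state[v]]
        total += prob
    return total


def beta_bin_means_quadrature(p: float, q: float, K: int) -> np.ndarray:
    """Conditional bin means of Beta(p, q) over K equal-probability bins,
    by adaptive quadrature of x * pdf(x) on each bin."""
    edges = beta_dist.ppf(np.linspace(0, 1, K + 1), p, q)
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        integral, _ = quad(lambda x: x * beta_dist.pdf(x, p, q), lo, hi,
                           limit=200, epsabs=1e-12, epsrel=1e-12)
        means.append(integral * K)   # each bin has probability 1/K
    return np.array(means)


def bh_stepup_rejections(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini–Hochberg rejection set at level alpha, from the definition:
    reject the k smallest p-values where k = max{i : p_(i) <= alpha i/m}."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k = 0
    for i in range(1, m + 1):
        if sorted_p[i - 1] <= alpha * i / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject
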