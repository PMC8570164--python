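"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from powerpost.models.phylo import (
    Alignment,
    GTRParams,
    Tree,
    build_rate_matrix,
    discrete_gamma_rates,
    transition_probs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def normal_model():
    from powerpost.models.reference import default_normal_model

    return default_normal_model()


@pytest.fixture
def betabinom_model():
    from powerpost.models.reference import default_betabinom_model

    return default_betabinom_model()


@pytest.fixture
def small_tree():
    return Tree.from_newick("((A:0.1,B:0.15):0.05,(C:0.2,(D:0.1,E:0.05):0.08):0.1):0.0;")


@pytest.fixture
def gtr_params():
    return GTRParams(
        exchangeabilities=np.array([0.1, 0.2, 0.15, 0.15, 0.25, 0.15]),
        base_freqs=np.array([0.3, 0.2, 0.25, 0.25]),
        gamma_shape=0.5,
    )


def all_rooted_topologies(labels: tuple[str, ...]) -> list[str]:
    """Every labeled rooted binary topology on the given leaves, as newick
    (without branch lengths).  3 labels -> 3 trees, 4 labels -> 15."""

    def build(subset: tuple[str, ...]) -> list[str]:
        if len(subset) == 1:
            return [subset[0] + ":0.1"]
        out = []
        rest = subset[1:]
        # unordered splits: first element always goes left
        for r in range(len(rest) + 1):
            for left_rest in itertools.combinations(rest, r):
                left = (subset[0],) + left_rest
                right = tuple(x for x in subset if x not in left)
                if not right:
                    continue
                for lt in build(left):
                    for rt in build(right):
                        out.append(f"({lt},{rt}):0.1")
        return out

    return [t.rsplit(":", 1)[0] + ";" for t in build(labels)]


def brute_force_log_likelihood(tree: Tree, aln: Alignment, params: GTRParams) -> float:
    """Exhaustive sum over all ancestral state assignments (test oracle)."""
    Q = build_rate_matrix(params)
    rates = discrete_gamma_rates(params.gamma_shape, params.n_categories)
    pi = params.base_freqs
    row = {name: i for i, name in enumerate(aln.taxa)}
    internals = [n for n in range(tree.n_nodes) if tree.children[n]]
    total = 0.0
    for site in range(aln.n_sites):
        leafstates = {
            n: [s for s in range(4) if aln.masks[row[lab], site] & (1 << s)]
            for n, lab in tree.leaf_labels.items()
        }
        site_lik = 0.0
        for r in rates:
            P = {n: transition_probs(Q, tree.edge_lengths[n], r, pi=pi) for n in tree.edge_nodes}
            for assign in itertools.product(range(4), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                p = pi[amap[tree.root]]
                for n in internals:
                    for c in tree.children[n]:
                        if c in amap:
                            p *= P[c][amap[n], amap[c]]
                        else:
                            p *= sum(P[c][amap[n], s] for s in leafstates[c])
                site_lik += p / len(rates)
        total += np.log(site_lik)
    return total


def batch_se(x: np.ndarray, n_batches: int = 20) -> float:
    """Standard error of the mean of a correlated series via batch means."""
    x = np.asarray(x, dtype=float)
    usable = (len(x) // n_batches) * n_batches
    batches = x[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
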