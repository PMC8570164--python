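import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import gamma as gamma_dist

import powerpost as pp
from powerpost.models.phylo import (
    Alignment,
    GTRParams,
    PhyloGTRModel,
    Tree,
    build_rate_matrix,
    discrete_gamma_rates,
    phylo_log_prior,
    pruning_log_likelihood,
    read_alignment,
    simulate_alignment,
    site_partition_log_likelihood,
    transition_probs,
)

from conftest import all_rooted_topologies, brute_force_log_likelihood


def jc_params(ncat=1, shape=1.0):
    return GTRParams(
        exchangeabilities=np.full(6, 1 / 6),
        base_freqs=np.full(4, 0.25),
        gamma_shape=shape,
        n_categories=ncat,
    )


def random_params(rng, ncat=4):
    return GTRParams(
        exchangeabilities=rng.dirichlet(np.ones(6) * 5),
        base_freqs=rng.dirichlet(np.ones(4) * 5),
        gamma_shape=float(rng.uniform(0.3, 2.0)),
        n_categories=ncat,
    )


class TestRateMatrix:
    def test_jukes_cantor_limit(self):
        Q = build_rate_matrix(jc_params())
        off = Q[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 1 / 3, atol=1e-14)
        np.testing.assert_allclose(np.diag(Q), -1.0, atol=1e-14)

    def test_detailed_balance_and_unit_rate(self, rng):
        for _ in range(5):
            params = random_params(rng)
            Q = build_rate_matrix(params)
            pi = params.base_freqs
            np.testing.assert_allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)
            np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            assert -float(pi @ np.diag(Q)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            GTRParams(np.full(6, 1 / 6), np.array([0.5, 0.5, 0.0, 0.0]))


class TestTransitionProbs:
    def test_zero_branch_is_identity(self, rng):
        params = random_params(rng)
        P = transition_probs(build_rate_matrix(params), 0.0, pi=params.base_freqs)
        np.testing.assert_allclose(P, np.eye(4), atol=1e-12)

    def test_jukes_cantor_closed_form(self):
        P = transition_probs(build_rate_matrix(jc_params()), 0.1, pi=np.full(4, 0.25))
        diag = 0.25 + 0.75 * math.exp(-0.4 / 3)
        np.testing.assert_allclose(np.diag(P), diag, atol=1e-12)
        np.testing.assert_allclose(P[~np.eye(4, dtype=bool)], (1 - diag) / 3, atol=1e-12)

    def test_long_branch_reaches_stationarity(self, rng):
        params = random_params(rng)
        P = transition_probs(build_rate_matrix(params), 500.0, pi=params.base_freqs)
        np.testing.assert_allclose(P, np.tile(params.base_freqs, (4, 1)), atol=1e-8)

    def test_rows_are_distributions(self, rng):
        params = random_params(rng)
        P = transition_probs(build_rate_matrix(params), 0.37, rate=1.7, pi=params.base_freqs)
        assert np.all(P >= 0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)


class TestDiscreteGamma:
    def test_mean_is_exactly_one(self):
        for shape in (0.1, 0.5, 1.0, 5.0):
            rates = discrete_gamma_rates(shape, 4)
            assert rates.mean() == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(rates) > 0)

    def test_degenerate_gamma_gives_unit_rates(self):
        np.testing.assert_allclose(discrete_gamma_rates(1e6, 4), 1.0, atol=1e-2)

    def test_category_means_of_unit_exponential(self):
        # shape=1: gamma(1,1) is a unit exponential; integrate each quartile
        rates = discrete_gamma_rates(1.0, 4)
        edges = gamma_dist.ppf([0, 0.25, 0.5, 0.75, 1.0], a=1.0)
        for j in range(4):
            hi = edges[j + 1] if np.isfinite(edges[j + 1]) else 60.0
            mean_j, _ = integrate.quad(lambda x: x * math.exp(-x), edges[j], hi)
            assert rates[j] == pytest.approx(mean_j / 0.25, rel=1e-6)


class TestPruning:
    def test_two_taxon_jc_closed_form(self):
        # one site with equal states; likelihood = 1/4 * (1/4 + 3/4 e^{-4t/3})
        tree = Tree.from_newick("(A:0.07,B:0.05);")
        aln = Alignment.from_sequences(["A", "B"], ["C", "C"])
        t = 0.12
        expected = math.log(0.25 * (0.25 + 0.75 * math.exp(-4 * t / 3)))
        assert pruning_log_likelihood(tree, aln, jc_params()) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_exhaustive_enumeration_on_all_small_topologies(self):
        """Pruning equals brute-force summation over ancestral states for
        every labeled rooted binary topology on 3 and 4 taxa."""
        rng = np.random.default_rng(77)
        case = 0
        for labels in (("A", "B", "C"), ("A", "B", "C", "D")):
            for newick in all_rooted_topologies(labels):
                tree = Tree.from_newick(newick)
                tree.edge_lengths[tree.edge_nodes] = rng.uniform(0.02, 0.5, tree.n_edges)
                params = random_params(rng)
                aln = simulate_alignment(tree, params, 3, seed=case)
                got = pruning_log_likelihood(tree, aln, params)
                want = brute_force_log_likelihood(tree, aln, params)
                assert got == pytest.approx(want, abs=1e-10), newick
                case += 1
        assert case == 18  # 3 + 15 topologies

    def test_missing_data_and_ambiguity(self, small_tree, gtr_params):
        aln = Alignment.from_sequences(
            ["A", "B", "C", "D", "E"], ["ACGT", "AC-T", "RCGT", "ANGT", "ACG?"]
        )
        ll = pruning_log_likelihood(small_tree, aln, gtr_params)
        assert np.isfinite(ll)
        # an all-missing column contributes log(1) = 0 likelihood mass times
        # the frequency sum, i.e. exactly zero extra information
        aln2 = Alignment.from_sequences(
            ["A", "B", "C", "D", "E"], ["ACGTN", "AC-TN", "RCGTN", "ANGTN", "ACG?N"]
        )
        ll2 = pruning_log_likelihood(small_tree, aln2, gtr_params)
        assert ll2 == pytest.approx(ll, abs=1e-10)

    def test_zero_length_duplicate_taxon(self, gtr_params):
        tree = Tree.from_newick("((A:0.0,B:0.0):0.1,C:0.2);")
        # A and B are forced identical by the zero branches: an identical
        # pair has the same likelihood as the single taxon alone
        pair = Alignment.from_sequences(["A", "B", "C"], ["G", "G", "T"])
        single_tree = Tree.from_newick("(A:0.1,C:0.2);")
        single = Alignment.from_sequences(["A", "C"], ["G", "T"])
        ll_pair = pruning_log_likelihood(tree, pair, gtr_params)
        ll_single = pruning_log_likelihood(single_tree, single, gtr_params)
        assert ll_pair == pytest.approx(ll_single, abs=1e-10)

    def test_site_order_and_compression_invariance(self, small_tree, gtr_params):
        aln = simulate_alignment(small_tree, gtr_params, 60, seed=9)
        perm = np.random.default_rng(1).permutation(60)
        shuffled = Alignment(taxa=aln.taxa, masks=aln.masks[:, perm])
        ll = pruning_log_likelihood(small_tree, aln, gtr_params)
        assert pruning_log_likelihood(small_tree, shuffled, gtr_params) == pytest.approx(
            ll, abs=1e-9
        )
        assert aln.pattern_weights.sum() == 60

    def test_taxon_mismatch_names_offenders(self, small_tree, gtr_params):
        aln = Alignment.from_sequences(["A", "B", "C", "D", "X"], ["A", "C", "G", "T", "A"])
        with pytest.raises(ValueError, match="X"):
            pruning_log_likelihood(small_tree, aln, gtr_params)


class TestSitePartition:
    def test_partition_is_bit_identical_for_any_n(self, small_tree, gtr_params):
        aln = simulate_alignment(small_tree, gtr_params, 12, seed=4)
        ll = pruning_log_likelihood(small_tree, aln, gtr_params)
        for N in (1, 2, 3, 4, 12):
            assert site_partition_log_likelihood(small_tree, aln, gtr_params, N) == ll

    def test_site_range_restricts_columns(self, small_tree, gtr_params):
        aln = simulate_alignment(small_tree, gtr_params, 20, seed=5)
        full = pruning_log_likelihood(small_tree, aln, gtr_params)
        left = pruning_log_likelihood(small_tree, aln, gtr_params, site_range=(0, 11))
        right = pruning_log_likelihood(small_tree, aln, gtr_params, site_range=(11, 20))
        assert left + right == pytest.approx(full, abs=1e-9)

    def test_too_many_blocks_rejected(self, small_tree, gtr_params):
        aln = simulate_alignment(small_tree, gtr_params, 5, seed=6)
        with pytest.raises(ValueError):
            site_partition_log_likelihood(small_tree, aln, gtr_params, 6)


class TestSimulator:
    def test_zero_length_star_gives_identical_taxa(self, gtr_params):
        tree = Tree.from_newick("((A:0.0,B:0.0):0.0,(C:0.0,D:0.0):0.0);")
        aln = simulate_alignment(tree, gtr_params, 30, seed=2)
        assert np.all(aln.masks == aln.masks[0])

    def test_long_branches_recover_stationary_frequencies(self):
        params = GTRParams(
            exchangeabilities=np.full(6, 1 / 6),
            base_freqs=np.array([0.4, 0.3, 0.2, 0.1]),
            gamma_shape=1.0,
            n_categories=1,
        )
        tree = Tree.from_newick("((A:30.0,B:30.0):30.0,(C:30.0,D:30.0):30.0);")
        n = 4000
        aln = simulate_alignment(tree, params, n, seed=7)
        counts = np.array([(aln.masks == b).sum() for b in (1, 2, 4, 8)]) / aln.masks.size
        se = np.sqrt(params.base_freqs * (1 - params.base_freqs) / (4 * n))
        assert np.all(np.abs(counts - params.base_freqs) < 4 * se)

    def test_seed_reproducibility(self, small_tree, gtr_params):
        a1 = simulate_alignment(small_tree, gtr_params, 40, seed=11)
        a2 = simulate_alignment(small_tree, gtr_params, 40, seed=11)
        np.testing.assert_array_equal(a1.masks, a2.masks)


class TestAlignmentIO:
    def test_fasta_round_trip(self, tmp_path, small_tree, gtr_params):
        aln = simulate_alignment(small_tree, gtr_params, 25, seed=3)
        path = tmp_path / "aln.fasta"
        aln.to_fasta(path)
        back = read_alignment(path)
        assert back.taxa == aln.taxa
        np.testing.assert_array_equal(back.masks, aln.masks)

    def test_relaxed_phylip(self, tmp_path):
        text = " 3 8\nTaxonOne  ACGTACGT\nTaxonTwo  ACGTACGA\nTaxonTri  ACGAACGT\n"
        path = tmp_path / "aln.phy"
        path.write_text(text)
        aln = read_alignment(path)
        assert aln.n_taxa == 3 and aln.n_sites == 8
        assert "TaxonOne" in aln.taxa


class TestPhyloModelContract:
    def test_log_prior_is_proper_and_finite(self, small_tree, gtr_params):
        lp = phylo_log_prior(small_tree, gtr_params)
        assert np.isfinite(lp)
        # exponential(10) branch prior: doubling total length drops the prior
        longer = small_tree.with_edge_lengths(
            2 * small_tree.edge_lengths[small_tree.edge_nodes]
        )
        assert phylo_log_prior(longer, gtr_params) < lp

    def test_end_to_end_estimator_consistency(self, small_tree, gtr_params):
        """Simulate data, run the full power posterior pipeline at reduced
        length, and require the two estimators to agree with each other and
        to be stable across seeds (the standard accuracy diagnostic)."""
        aln = simulate_alignment(small_tree, gtr_params, 120, seed=13)
        model = PhyloGTRModel(tree=small_tree, alignment=aln)
        sched = pp.make_powers(20)
        results = []
        for seed in (0, 1):
            cfg = pp.StoneRunConfig(L=240, T=4, burnin_frac=0.25, preburn_iters=240, seed=seed)
            sm = pp.run_sequential(model, sched, cfg)
            ps, ss, gap = pp.estimate_both(sm)
            assert gap < 0.5
            results.append((ps.log_ml, ss.log_ml))
        assert abs(results[0][0] - results[1][0]) < 1.0
        assert abs(results[0][1] - results[1][1]) < 1.0
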