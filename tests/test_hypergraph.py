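import numpy as np
import pytest
from scipy import stats

import wgchna as w
from wgchna.io import ExpressionMatrix
from wgchna.hypergraph import pairwise_mutual_information

from conftest import random_expression, random_hypergraph
from oracles import naive_edge_weights_corr, naive_mi_matrix


class TestToyHypergraph:
    def test_printed_structure(self):
        hg = w.toy_hypergraph()
        assert hg.n_nodes == 7
        assert hg.n_edges == 4
        np.testing.assert_array_equal(hg.edge_weights, [3, 2, 2, 2])
        assert hg.edge_weights.sum() == 9

    def test_edge_memberships(self):
        hg = w.toy_hypergraph()
        col_e4 = hg.incidence[:, 3]
        assert col_e4.sum() == 2
        assert col_e4[3] == 1 and col_e4[6] == 1  # v4 and v7
        np.testing.assert_array_equal(w.edge_degrees(hg), [3, 2, 2, 2])

    def test_hyperdegrees_from_printed_weights(self):
        hg = w.toy_hypergraph()
        d = w.node_hyperdegrees(hg)
        assert d[2] == 5  # v3 in e1 and e2: 3 + 2
        assert d[3] == 2  # v4 only in e4


class TestBuildIncidence:
    def test_tau_zero_all_ones(self):
        rng = np.random.default_rng(21)
        Z = w.standardize(random_expression(rng, 6, 8))
        hg = w.build_incidence(Z, tau=0.0)
        np.testing.assert_array_equal(hg.incidence, np.ones((6, 8)))

    def test_threshold_membership(self):
        # two genes so edges always have >= 2 members where both pass
        Z = ExpressionMatrix(
            np.array([[2.0, 0.1], [-1.5, -2.0]]), ["a", "b"], ["s1", "s2"]
        )
        hg = w.build_incidence(Z, tau=1.0)
        # edge s2 has a single member (only b passes) and is dropped
        assert hg.edge_ids == ["s1"]
        np.testing.assert_array_equal(hg.incidence, [[1.0], [1.0]])

    def test_membership_fraction_matches_normal_tail(self):
        rng = np.random.default_rng(22)
        Z = w.standardize(random_expression(rng, 50, 10))
        hg = w.build_incidence(Z, tau=1.0)
        frac = hg.incidence.mean()
        expected = 2 * (1 - stats.norm.cdf(1))  # ~0.3173
        assert abs(frac - expected) < 0.06

    def test_all_edges_dropped_error(self):
        Z = ExpressionMatrix(np.zeros((3, 2)), list("abc"), ["s1", "s2"])
        with pytest.raises(ValueError, match="tau"):
            w.build_incidence(Z, tau=5.0)


class TestCorrWeights:
    def test_single_perfect_pair(self):
        values = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        X = ExpressionMatrix(values, ["a", "b"], ["s1", "s2", "s3"])
        hg = w.WeightedHypergraph(np.ones((2, 3)), np.ones(3), ["a", "b"], ["s1", "s2", "s3"])
        for beta in (1, 4, 9):
            out = w.hyperedge_weights_corr(X, hg, beta=beta)
            np.testing.assert_allclose(out.edge_weights, 1.0, atol=1e-12)

    def test_three_gene_edge_mean(self):
        # precomputed |corr| matrix path: feed corr directly
        hg = w.WeightedHypergraph(
            np.ones((3, 2)), np.ones(2), list("abc"), ["s1", "s2"]
        )
        corr = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
        out = w.hyperedge_weights_corr(None, hg, beta=1, corr=corr)
        np.testing.assert_allclose(out.edge_weights, [0.4, 0.4], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, hg = random_hypergraph(rng, 30, 12, tau=1.0, beta=6)
        expected = naive_edge_weights_corr(X.values, hg.incidence, beta=6)
        np.testing.assert_allclose(hg.edge_weights, expected, atol=1e-10)

    def test_monotone_nonincreasing_in_beta(self):
        rng = np.random.default_rng(23)
        X, hg1 = random_hypergraph(rng, 20, 10, beta=1)
        previous = hg1.edge_weights
        for beta in (2, 4, 8):
            current = w.hyperedge_weights_corr(X, hg1, beta=beta).edge_weights
            assert (current <= previous + 1e-12).all()
            previous = current

    def test_handshake_identity(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            _, hg = random_hypergraph(rng, 25, 8)
            lhs = w.node_hyperdegrees(hg).sum()
            rhs = (hg.edge_weights * w.edge_degrees(hg)).sum()
            np.testing.assert_allclose(lhs, rhs, rtol=1e-12)


class TestMutualInformationWeights:
    def test_independent_genes_near_zero(self):
        # designed orthogonal two-level patterns: joint table is uniform
        values = np.array(
            [[0.0, 0.0, 1.0, 1.0], [0.0, 1.0, 0.0, 1.0]]
        )
        mi = pairwise_mutual_information(values, bins=2)
        assert abs(mi[0, 1]) < 1e-12

    def test_duplicated_gene_gives_log2(self):
        values = np.array([[0.0, 1.0, 0.0, 1.0], [0.0, 1.0, 0.0, 1.0]])
        mi = pairwise_mutual_information(values, bins=2)
        np.testing.assert_allclose(mi[0, 1], np.log(2), atol=1e-10)

    def test_matches_contingency_oracle(self):
        rng = np.random.default_rng(31)
        X, hg = random_hypergraph(rng, 15, 12)
        mi_fast = pairwise_mutual_information(X.values, bins=4)
        mi_slow = naive_mi_matrix(X.values, bins=4)
        np.testing.assert_allclose(mi_fast, mi_slow, atol=1e-10)
        # and the per-edge aggregation
        edge_mi = w.hyperedge_weights_mi(X, hg, bins=4)
        for e in range(hg.n_edges):
            members = hg.edge_members(e)
            vals = [mi_slow[i, j] for i in members for j in members if i < j]
            np.testing.assert_allclose(edge_mi[e], np.mean(vals), atol=1e-10)

    def test_constant_gene_error(self):
        values = np.vstack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="constant"):
            pairwise_mutual_information(values, bins=2)


class TestCompareWeightSchemes:
    def test_report_consistency(self):
        rng = np.random.default_rng(41)
        X, hg = random_hypergraph(rng, 20, 12)
        report = w.compare_weight_schemes(X, hg, beta=2, bins=4)
        assert report.corr_weights.shape == report.mi_weights.shape
        rho, p = stats.spearmanr(report.corr_weights, report.mi_weights)
        np.testing.assert_allclose(report.spearman_rho, rho, atol=1e-12)
        np.testing.assert_allclose(report.spearman_p, p, atol=1e-12)

    def test_too_few_edges_error(self):
        hg = w.toy_hypergraph()
        with pytest.raises(ValueError, match="5 hyperedges"):
            w.compare_weight_schemes(None, hg)


class TestSerialization:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(51)
        _, hg = random_hypergraph(rng, 12, 6)
        edges, weights = tmp_path / "edges.tsv", tmp_path / "weights.tsv"
        from wgchna.hypergraph import read_hypergraph, write_hypergraph

        write_hypergraph(hg, edges, weights)
        back = read_hypergraph(edges, weights)
        assert back.edge_ids == hg.edge_ids
        assert set(back.node_ids) == set(hg.node_ids)
        reorder = [back.node_ids.index(g) for g in hg.node_ids]
        np.testing.assert_array_equal(back.incidence[reorder], hg.incidence)
        np.testing.assert_allclose(back.edge_weights, hg.edge_weights, rtol=1e-15)
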