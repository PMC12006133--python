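import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

import wgchna as w
from wgchna.io import ExpressionMatrix
from wgchna.laplacian import DissTOM
from wgchna.modules import DetectionConfig, renumber_by_size

from oracles import naive_average_linkage_cophenetic


def block_dissimilarity(sizes, within=0.1, between=0.9, jitter=0.02, seed=0):
    """Symmetric planted-block dissimilarity with small deterministic jitter."""
    n = sum(sizes)
    rng = np.random.default_rng(seed)
    D = np.full((n, n), between)
    start = 0
    truth = np.zeros(n, dtype=int)
    for k, size in enumerate(sizes, start=1):
        D[start:start + size, start:start + size] = within
        truth[start:start + size] = k
        start += size
    noise = rng.uniform(-jitter, jitter, size=(n, n))
    D = D + (noise + noise.T) / 2
    np.fill_diagonal(D, 0.0)
    ids = [f"g{i}" for i in range(n)]
    return DissTOM(D, ids), truth


class TestHierarchicalCluster:
    def test_two_points_single_merge(self):
        d = DissTOM(np.array([[0.0, 0.4], [0.4, 0.0]]), ["a", "b"])
        dend = w.hierarchical_cluster(d)
        assert dend.shape == (1, 4)
        np.testing.assert_allclose(dend[0, 2], 0.4)

    def test_separated_groups_merge_last(self):
        d, _ = block_dissimilarity([5, 5], within=0.05, between=0.95, jitter=0.0)
        dend = w.hierarchical_cluster(d)
        heights = dend[:, 2]
        assert heights[-1] > 0.9
        assert heights[:-1].max() < 0.1

    def test_cophenetic_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        M = rng.uniform(0.1, 1.0, size=(30, 30))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        d = DissTOM(D, [f"g{i}" for i in range(30)])
        dend = w.hierarchical_cluster(d)
        coph = squareform(cophenet(dend))
        expected = naive_average_linkage_cophenetic(D)
        np.testing.assert_allclose(coph, expected, atol=1e-10)

    def test_nonfinite_error(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            w.hierarchical_cluster(DissTOM(D, ["a", "b"]))


class TestCutTreeDynamic:
    def test_no_structure_all_grey(self):
        rng = np.random.default_rng(5)
        noise = rng.uniform(-0.01, 0.01, size=(100, 100))
        D = np.full((100, 100), 1.0) + (noise + noise.T) / 2
        np.fill_diagonal(D, 0.0)
        dend = w.hierarchical_cluster(DissTOM(D, [f"g{i}" for i in range(100)]))
        labels = w.cut_tree_dynamic(dend, DetectionConfig(min_cluster_size=50))
        assert (labels == 0).all()

    def test_planted_blocks_recovered(self):
        d, truth = block_dissimilarity([60, 60, 60, 60], seed=1)
        dend = w.hierarchical_cluster(d)
        labels = w.cut_tree_dynamic(dend, DetectionConfig())
        assert len(set(labels.tolist()) - {0}) == 4
        sizes = sorted(np.bincount(labels)[1:])
        assert sizes == [60, 60, 60, 60]
        ext = w.external_metrics(labels, truth)
        assert ext.ari == 1.0

    def test_deeper_split_refines(self):
        d, _ = block_dissimilarity([30, 30, 30, 30], within=0.2, between=0.8, seed=2)
        dend = w.hierarchical_cluster(d)
        shallow = w.cut_tree_dynamic(dend, DetectionConfig(min_cluster_size=10, deep_split=0))
        deep = w.cut_tree_dynamic(dend, DetectionConfig(min_cluster_size=10, deep_split=3))
        assert len(set(deep.tolist()) - {0}) >= len(set(shallow.tolist()) - {0})


class TestModuleEigengenes:
    def test_duplicated_genes_rank_one(self):
        rng = np.random.default_rng(7)
        profile = rng.standard_normal(20)
        values = np.tile(profile, (5, 1)) * rng.uniform(1, 3, size=(5, 1))
        X = ExpressionMatrix(values, [f"g{i}" for i in range(5)], [f"s{j}" for j in range(20)])
        ME = w.module_eigengenes(X, np.ones(5, dtype=int))
        for g in range(5):
            r = np.corrcoef(ME["ME1"], values[g])[0, 1]
            np.testing.assert_allclose(abs(r), 1.0, atol=1e-10)
            assert r > 0  # oriented along the module mean profile

    def test_orientation_deterministic(self):
        rng = np.random.default_rng(8)
        X = ExpressionMatrix(
            rng.standard_normal((10, 15)), [f"g{i}" for i in range(10)], [f"s{j}" for j in range(15)]
        )
        labels = np.ones(10, dtype=int)
        a = w.module_eigengenes(X, labels)
        b = w.module_eigengenes(X, labels)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
        # eigengene correlates nonnegatively with the module mean profile
        Z = w.standardize(X)
        mean_profile = Z.values.mean(axis=0)
        assert np.corrcoef(a["ME1"], mean_profile)[0, 1] >= 0

    def test_planted_factor_recovered(self, default_dataset):
        ds = default_dataset
        ME = w.module_eigengenes(ds.expression, ds.truth)
        for k in range(1, 5):
            r = np.corrcoef(ME[f"ME{k}"], ds.factors[:, k - 1])[0, 1]
            assert abs(r) >= 0.95

    def test_singleton_module_is_standardized_profile(self):
        rng = np.random.default_rng(9)
        X = ExpressionMatrix(
            rng.standard_normal((3, 12)), ["a", "b", "c"], [f"s{j}" for j in range(12)]
        )
        labels = np.array([1, 1, 2])
        ME = w.module_eigengenes(X, labels)
        r = np.corrcoef(ME["ME2"], X.values[2])[0, 1]
        np.testing.assert_allclose(r, 1.0, atol=1e-10)


class TestMergeSimilarModules:
    def test_split_module_restored(self, default_dataset):
        ds = default_dataset
        labels = ds.truth.copy()
        members = np.where(labels == 1)[0]
        labels[members[: members.size // 2]] = 9
        merged = w.merge_similar_modules(ds.expression, labels, 0.8)
        assert len(set(merged.tolist()) - {0}) == 4

    def test_orthogonal_modules_not_merged(self, default_dataset):
        ds = default_dataset
        merged = w.merge_similar_modules(ds.expression, ds.truth.copy(), 0.8)
        np.testing.assert_array_equal(merged, ds.truth)

    def test_threshold_one_is_noop(self, default_dataset):
        ds = default_dataset
        labels = ds.truth.copy()
        members = np.where(labels == 1)[0]
        labels[members[:30]] = 9
        merged = w.merge_similar_modules(ds.expression, labels, 1.0)
        np.testing.assert_array_equal(merged, labels)

    def test_larger_label_wins(self, default_dataset):
        ds = default_dataset
        labels = ds.truth.copy()
        members = np.where(labels == 2)[0]
        labels[members[:10]] = 9  # small splinter, label 9
        merged = w.merge_similar_modules(ds.expression, labels, 0.8)
        assert (merged[members] == 2).all()


class TestDetectModules:
    def fixture(self):
        d, truth = block_dissimilarity([60, 60, 60, 60], seed=3)
        rng = np.random.default_rng(30)
        factors = rng.standard_normal((20, 4))
        values = np.empty((240, 20))
        for i in range(240):
            values[i] = 0.9 * factors[:, truth[i] - 1] + 0.4 * rng.standard_normal(20)
        X = ExpressionMatrix(values, d.node_ids, [f"s{j}" for j in range(20)])
        return X, d, truth

    def test_end_to_end_determinism_and_recovery(self):
        X, d, truth = self.fixture()
        a = w.detect_modules(X, d)
        b = w.detect_modules(X, d)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.n_modules == 4
        assert w.external_metrics(a.labels, truth).ari == 1.0

    def test_gene_permutation_gives_same_partition(self):
        X, d, truth = self.fixture()
        rng = np.random.default_rng(31)
        perm = rng.permutation(240)
        Xp = ExpressionMatrix(X.values[perm], [X.gene_ids[i] for i in perm], list(X.sample_ids))
        dp = DissTOM(d.diss[np.ix_(perm, perm)], [d.node_ids[i] for i in perm])
        a = w.detect_modules(X, d)
        b = w.detect_modules(Xp, dp)
        assert w.external_metrics(a.labels[perm], b.labels).ari == 1.0

    def test_renumber_by_size(self):
        labels = np.array([3, 3, 3, 7, 7, 0, 5])
        out = renumber_by_size(labels)
        np.testing.assert_array_equal(out, [1, 1, 1, 2, 2, 0, 3])
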