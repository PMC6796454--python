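"""PCA embedding, Ward cut selection, v-statistic and NMI diagnostics."""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import normalized_mutual_info_score

import gliosig as gs
from gliosig.errors import ConfigurationError, ValidationError


def blobs(rng, centers, n_per, sd=1.0):
    pts = np.vstack([rng.normal(c, sd, size=(n_per, len(c))) for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return pts, labels


class TestPCA:
    def test_collinear_data_explained_by_one_component(self, rng):
        t = rng.normal(size=50)
        x = np.outer(t, [1.0, 2.0, -0.5])
        emb = gs.pca_embed(x, 2)
        total = emb.explained_variance.sum()
        assert emb.explained_variance[0] / total == pytest.approx(1.0, abs=1e-12)

    def test_two_cell_scores_symmetric(self):
        emb = gs.pca_embed(np.array([[0.0, 0.0], [2.0, 2.0]]), 1)
        assert emb.scores.sum() == pytest.approx(0.0, abs=1e-12)

    def test_full_rank_reconstruction(self, rng):
        x = rng.normal(size=(20, 6))
        emb = gs.pca_embed(x, 6)
        recon = emb.scores @ emb.components + emb.mean
        assert np.abs(recon - x).max() < 1e-8

    def test_bad_component_count_raises(self, rng):
        with pytest.raises(ConfigurationError):
            gs.pca_embed(rng.normal(size=(5, 3)), 5)


class TestHCPC:
    def test_two_separated_blobs(self, rng):
        pts, labels = blobs(rng, [(0, 0), (10, 10)], 30)
        assignment = gs.hcpc_cluster(gs.pca_embed(pts, 2))
        assert assignment.k == 2
        assert gs.nmi(assignment.labels, labels).value == 1.0

    def test_three_blobs_recovered(self, rng):
        pts, labels = blobs(rng, [(0, 0), (8, 0), (0, 8)], 20)
        assignment = gs.hcpc_cluster(gs.pca_embed(pts, 2))
        assert assignment.k == 3
        assert gs.nmi(assignment.labels, labels).value == 1.0

    def test_identical_cells_raise(self):
        emb = gs.Embedding(scores=np.zeros((30, 2)), explained_variance=np.zeros(2), n_components=2)
        with pytest.raises(ConfigurationError, match="inertia"):
            gs.hcpc_cluster(emb)

    def test_deterministic(self, rng):
        pts, _ = blobs(rng, [(0, 0), (6, 1), (3, 7)], 25)
        emb = gs.pca_embed(pts, 2)
        a = gs.hcpc_cluster(emb, consolidate=True)
        b = gs.hcpc_cluster(emb, consolidate=True)
        assert np.array_equal(a.labels, b.labels)


class TestDescribeClusters:
    def test_matches_direct_formula(self):
        x = np.array([[1.0], [2.0], [3.0], [7.0], [8.0], [9.0]])
        clusters = gs.ClusterAssignment(labels=np.array([0, 0, 0, 1, 1, 1]), k=2)
        table = gs.describe_clusters(x, clusters, p_threshold=1.0)
        n, nk = 6, 3
        s2 = x.var()
        expected_v = (x[:3].mean() - x.mean()) / np.sqrt(((n - nk) / (n - 1)) * s2 / nk)
        got = table[(table["cluster"] == 0)]["v"].iloc[0]
        assert got == pytest.approx(expected_v, abs=1e-12)
        assert table[(table["cluster"] == 0)]["direction"].iloc[0] == "down"

    def test_equal_means_not_reported(self):
        x = np.array([[1.0], [2.0], [1.0], [2.0]])
        clusters = gs.ClusterAssignment(labels=np.array([0, 0, 1, 1]), k=2)
        table = gs.describe_clusters(x, clusters, p_threshold=0.05)
        assert table.empty

    def test_threshold_one_reports_everything(self, rng):
        x = rng.normal(size=(12, 4))
        clusters = gs.ClusterAssignment(labels=np.array([0, 1] * 6), k=2)
        table = gs.describe_clusters(x, clusters, p_threshold=1.0)
        assert len(table) == 2 * 4

    def test_single_cluster_raises(self, rng):
        clusters = gs.ClusterAssignment(labels=np.zeros(5, dtype=int), k=1)
        with pytest.raises(ValidationError):
            gs.describe_clusters(rng.normal(size=(5, 2)), clusters)


def iter_partitions(n):
    """All set partitions of range(n) as label vectors (restricted growth strings)."""
    def rec(prefix, k):
        i = len(prefix)
        if i == n:
            yield tuple(prefix)
            return
        for lab in range(k + 1):
            yield from rec(prefix + [lab], max(k, lab + 1))
    yield from rec([], 0)


class TestNMI:
    def test_identical_partitions_give_exactly_one(self):
        labels = np.repeat(np.arange(4), 25)
        renamed = (labels + 2) % 4  # identical up to relabeling
        assert gs.nmi(labels, renamed).value == 1.0

    def test_balanced_partitions_give_exactly_zero(self):
        labels = np.tile(np.repeat(np.arange(4), 25), 4)
        clusters = np.repeat(np.arange(4), 100)
        assert gs.nmi(clusters, labels).value == 0.0

    def test_hand_computed_contingency_oracle(self):
        # table [[2,0],[1,1]]: H(a)=H(b)=ln 2, I = 0.5 ln2 + 0.25 ln2 ... by hand:
        a, b = [0, 0, 1, 1], [0, 0, 0, 1]
        pa = pb = np.array([0.5, 0.5])
        pb = np.array([0.75, 0.25])
        h_a = -np.sum(pa * np.log(pa))
        h_b = -np.sum(pb * np.log(pb))
        pij = np.array([[0.5, 0.0], [0.25, 0.25]])
        mi = sum(
            pij[i, j] * np.log(pij[i, j] / (pa[i] * pb[j]))
            for i in range(2)
            for j in range(2)
            if pij[i, j] > 0
        )
        expected = mi / np.sqrt(h_a * h_b)
        res = gs.nmi(a, b)
        assert res.value == pytest.approx(expected, abs=1e-12)
        assert res.entropy_a == pytest.approx(h_a, abs=1e-12)

    def test_symmetry_and_permutation_invariance(self, rng):
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 4, 40)
        assert gs.nmi(a, b).value == pytest.approx(gs.nmi(b, a).value, abs=1e-12)
        remap = np.array([2, 0, 3, 1])
        assert gs.nmi(a, remap[b]).value == pytest.approx(gs.nmi(a, b).value, abs=1e-12)

    def test_zero_entropy_flagged(self):
        res = gs.nmi([0, 0, 0], [0, 1, 2])
        assert res.value == 0.0 and res.degenerate

    def test_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            gs.nmi([0, 1], [0, 1, 2])

    def test_agreement_with_sklearn_reference(self, rng):
        for _ in range(50):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 3, 30)
            ours = gs.nmi(a, b).value
            ref = normalized_mutual_info_score(a, b, average_method="geometric")
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_brute_force_partitions_of_five(self):
        parts = list(iter_partitions(5))
        for a, b in itertools.islice(itertools.product(parts, parts), 0, None, 7):
            res = gs.nmi(a, b)
            if res.degenerate:  # a single-cluster partition: NMI defined as 0
                assert res.value == 0.0
                continue
            ref = normalized_mutual_info_score(a, b, average_method="geometric")
            assert res.value == pytest.approx(ref, abs=1e-10)


class TestDownsampling:
    def test_full_size_reproduces_reference_exactly(self, rng):
        pts, labels = blobs(rng, [(0, 0, 0), (6, 6, 0)], 25)
        assignment = gs.cluster_matrix(pts, n_components=2, k_max=5)
        full = gs.nmi(assignment.labels, labels).value
        report = gs.downsampling_experiment(
            pts, labels, reference_nmi=full, sizes=[3], reps=3, seed=0,
            n_components=2, k_max=5,
        )
        assert np.allclose(report.nmis[3], full)

    def test_degenerate_t_test_flagged(self, rng):
        pts, labels = blobs(rng, [(0, 0, 0), (9, 9, 0)], 25)
        report = gs.downsampling_experiment(
            pts, labels, reference_nmi=1.0, sizes=[3], reps=4, seed=0,
            n_components=2, k_max=5,
        )
        row = report.table.loc[3]
        assert row["degenerate"] and row["p"] == 1.0

    def test_size_above_gene_count_raises(self, rng):
        with pytest.raises(ConfigurationError):
            gs.downsampling_experiment(
                rng.normal(size=(30, 5)), np.zeros(30), 0.0, sizes=[10], reps=2, seed=0
            )
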