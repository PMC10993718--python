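import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from orthomap.errors import ConfigurationError
from orthomap.expression_harmonization import CellMatrix
from orthomap.integration_metrics import (
    BCS_COMPONENTS,
    SMS_COMPONENTS,
    Embedding,
    batch_asw,
    cell_cycle_conservation,
    clisi_norm,
    composite_scores,
    graph_connectivity,
    ilisi_norm,
    kbet_acceptance,
    knn_adjacency,
    knn_indices,
    isolated_label_f1,
    lisi,
    nmi,
    pca_embed,
    pca_of_matrix,
    pcr_comparison,
    silhouette_mean,
    snn_cluster,
    species_center,
)


def _embedding(coords):
    return Embedding(coordinates=np.asarray(coords, dtype=float))


def _blobs(rng, centers, n_per, d=2, spread=0.3):
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, spread, size=(n_per, d)))
        labels += [i] * n_per
    return np.vstack(pts), np.array(labels)


def _cell_matrix(X, species=None, cell_type=None):
    n_genes, n_cells = X.shape
    cells = [f"c{i}" for i in range(n_cells)]
    meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    meta["sample"] = "s"
    meta["species"] = species if species is not None else "a"
    meta["condition"] = "na"
    if cell_type is not None:
        meta["cell_type"] = cell_type
    return CellMatrix(
        counts=np.asarray(X, dtype=float),
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=cells,
        cell_meta=meta,
    )


class TestPCA:
    def test_duplicate_cells_identical_rows(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(3.0, size=(40, 20)).astype(float)
        X[:, 5] = X[:, 4]
        m = _cell_matrix(X)
        emb = pca_embed(m, n_hvg=40, n_pcs=5)
        assert np.allclose(emb.coordinates[4], emb.coordinates[5], atol=1e-8)

    def test_dominant_axis_is_pc1(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(100, 1)) @ np.array([[5.0, 0.0, 0.0]])
        X = base + rng.normal(scale=0.1, size=(100, 3))
        emb = pca_of_matrix(X, n_pcs=2)
        var = emb.coordinates.var(axis=0)
        assert var[0] > 10 * var[1]

    def test_rotation_spans_same_subspace(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4)) @ np.diag([5, 3, 1, 0.5])
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        A = pca_of_matrix(X, n_pcs=2).coordinates
        B = pca_of_matrix(X @ q, n_pcs=2).coordinates
        # principal angles between the two column spaces are ~0
        qa, _ = np.linalg.qr(A)
        qb, _ = np.linalg.qr(B)
        sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
        assert np.allclose(sv, 1.0, atol=1e-6)

    def test_npcs_bound_enforced(self):
        m = _cell_matrix(np.ones((5, 4)) + np.eye(5, 4))
        with pytest.raises(ConfigurationError):
            pca_embed(m, n_pcs=10)


class TestClustering:
    def test_two_separated_blobs_two_clusters(self):
        rng = np.random.default_rng(3)
        X, truth = _blobs(rng, [(0, 0), (30, 30)], 60)
        labels = snn_cluster(_embedding(X), k=15, resolution=0.3, seed=0)
        assert len(np.unique(labels)) == 2
        assert nmi(labels, truth) == pytest.approx(1.0)

    def test_order_equivariance(self):
        rng = np.random.default_rng(4)
        X, _ = _blobs(rng, [(0, 0), (20, 20), (0, 20)], 40)
        perm = rng.permutation(len(X))
        a = snn_cluster(_embedding(X), k=10, seed=1)
        b = snn_cluster(_embedding(X[perm]), k=10, seed=1)
        assert nmi(a[perm], b) == pytest.approx(1.0)

    def test_invalid_k(self):
        with pytest.raises(ConfigurationError):
            snn_cluster(_embedding(np.zeros((5, 2))), k=0)


class TestSilhouette:
    def test_hand_computed_four_points(self):
        # 1-D points 0, 1, 10, 11 in clusters {0,0,1,1}
        e = _embedding([[0.0], [1.0], [10.0], [11.0]])
        s0 = (10.5 - 1.0) / 10.5
        s1 = (9.5 - 1.0) / 9.5
        expected = (2 * s0 + 2 * s1) / 4  # symmetric
        assert silhouette_mean(e, [0, 0, 1, 1]) == pytest.approx(expected)

    def test_tight_separated_blobs_near_one(self):
        rng = np.random.default_rng(5)
        X, labels = _blobs(rng, [(0, 0), (1000, 1000)], 50, spread=0.01)
        assert silhouette_mean(_embedding(X), labels) > 0.99

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 2))
        labels = rng.integers(0, 2, size=200)
        assert abs(silhouette_mean(_embedding(X), labels)) < 0.1

    def test_single_label_is_error(self):
        with pytest.raises(ConfigurationError):
            silhouette_mean(_embedding(np.zeros((4, 2))), [0, 0, 0, 0])


class TestBatchASW:
    def test_hand_computed_six_points(self):
        # one group; batches fully separated on a line
        e = _embedding([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        batch = ["a", "a", "a", "b", "b", "b"]
        sil = []
        pts = [0.0, 1.0, 2.0, 10.0, 11.0, 12.0]
        for i, p in enumerate(pts):
            own = [abs(p - q) for j, q in enumerate(pts) if batch[j] == batch[i] and j != i]
            other = [abs(p - q) for j, q in enumerate(pts) if batch[j] != batch[i]]
            a, b = np.mean(own), np.mean(other)
            sil.append((b - a) / max(a, b))
        expected = float(np.mean([1 - abs(s) for s in sil]))
        got = batch_asw(e, batch, ["g"] * 6)
        assert got == pytest.approx(expected)
        assert got < 0.2  # fully separated batches: poor mixing

    def test_interleaved_batches_near_one(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 2))
        batch = np.tile(["a", "b"], 100)
        assert batch_asw(_embedding(X), batch, np.zeros(200)) > 0.8

    def test_single_batch_group_scores_one(self):
        e = _embedding(np.arange(8).reshape(4, 2))
        assert batch_asw(e, ["a"] * 4, ["g"] * 4) == 1.0


class TestGraphConnectivity:
    def _adj(self, edges, n):
        A = np.zeros((n, n))
        for i, j in edges:
            A[i, j] = A[j, i] = 1
        return sp.csr_matrix(A)

    def test_split_group_eight_two(self):
        # group of 10 split into components of sizes 8 and 2 -> 0.8
        edges = [(i, i + 1) for i in range(7)] + [(8, 9)]
        A = self._adj(edges, 10)
        assert graph_connectivity(A, np.zeros(10)) == pytest.approx(0.8)

    def test_connected_groups_and_singleton(self):
        edges = [(0, 1), (1, 2), (3, 4)]
        A = self._adj(edges, 6)
        groups = np.array([0, 0, 0, 1, 1, 2])
        assert graph_connectivity(A, groups) == pytest.approx(1.0)


class TestPCRegression:
    def test_identical_pre_post_is_zero(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 10))
        cov = rng.integers(0, 2, size=80).astype(str)
        assert pcr_comparison(X, X, cov) == 0.0

    def test_removing_covariate_axis_scores_high(self):
        rng = np.random.default_rng(9)
        cov = np.repeat([0.0, 10.0], 50)
        X = np.outer(cov - cov.mean(), np.ones(5)) + rng.normal(
            scale=0.05, size=(100, 5)
        )
        post = X - X.mean(axis=0)
        post[:50] -= post[:50].mean(axis=0)
        post[50:] -= post[50:].mean(axis=0)
        assert pcr_comparison(X, post, cov.astype(str)) > 0.95

    def test_orthogonal_covariate_degenerate(self):
        X = np.column_stack([np.tile([1.0, -1.0], 10), np.zeros(20)])
        cov = np.repeat([0, 1], 10).astype(str)  # orthogonal to the data axis
        with pytest.warns(UserWarning, match="no variance"):
            assert pcr_comparison(X, X + 1.0, cov) == 0.0


class TestCellCycleConservation:
    def test_post_equals_pre_is_one(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 8))
        cc = rng.random(60)
        assert cell_cycle_conservation(X, X, cc) == 1.0

    def test_covariate_variance_removed_scores_zero(self):
        rng = np.random.default_rng(11)
        cc = rng.random(100)
        X = np.outer(cc - cc.mean(), [3.0, 1.0, 0.5]) + rng.normal(
            scale=0.01, size=(100, 3)
        )
        post = rng.normal(size=(100, 3)) * 1e-6  # nothing left to explain
        assert cell_cycle_conservation(X, post, cc) < 0.05

    def test_zero_variance_pre_reports_one_with_warning(self):
        X = np.zeros((20, 3))
        with pytest.warns(UserWarning):
            assert cell_cycle_conservation(X, X, np.random.default_rng(0).random(20)) == 1.0


class TestLISI:
    def test_single_label_all_ones(self):
        e = _embedding(np.arange(20).reshape(10, 2))
        assert np.allclose(lisi(e, ["x"] * 10), 1.0)

    def test_interleaved_line_mixing(self):
        x = np.arange(200, dtype=float).reshape(-1, 1)
        labels = np.tile(["a", "b"], 100)
        raw = lisi(_embedding(x), labels, perplexity=30)
        assert np.median(raw) > 1.8
        assert ilisi_norm(_embedding(x), labels) > 0.8

    def test_separated_species_no_mixing(self):
        x = np.concatenate([np.arange(100), np.arange(100) + 10_000]).reshape(-1, 1)
        labels = np.repeat(["a", "b"], 100)
        assert ilisi_norm(_embedding(x.astype(float)), labels) < 0.05
        assert clisi_norm(_embedding(x.astype(float)), labels) > 0.95

    def test_range_and_single_batch_fallback(self):
        e = _embedding(np.random.default_rng(1).normal(size=(50, 3)))
        with pytest.warns(UserWarning, match="single batch"):
            assert ilisi_norm(e, ["only"] * 50) == 0.0


class TestKBET:
    def test_single_batch_accepts_everything(self):
        e = _embedding(np.random.default_rng(2).normal(size=(30, 2)))
        idx = knn_indices(e, 10)
        assert kbet_acceptance(idx, ["a"] * 30, seed=0) == 1.0

    def test_interleaved_high_separated_low(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 2))
        inter = np.tile(["a", "b"], 150)
        idx = knn_indices(_embedding(X), 30)
        assert kbet_acceptance(idx, inter, seed=0) > 0.85
        X2 = np.vstack([rng.normal(0, 1, (150, 2)), rng.normal(50, 1, (150, 2))])
        sep = np.repeat(["a", "b"], 150)
        idx2 = knn_indices(_embedding(X2), 30)
        assert kbet_acceptance(idx2, sep, seed=0) < 0.05


class TestIsolatedLabelF1:
    def test_separable_isolated_label_high(self):
        rng = np.random.default_rng(4)
        X, types = _blobs(rng, [(0, 0), (25, 25), (50, 0)], 50)
        labels = np.array([f"t{t}" for t in types])
        batch = np.where(labels == "t2", "only_a", np.tile(["a", "b"], 75))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = isolated_label_f1(_embedding(X), labels, batch, seed=0)
        assert score > 0.9

    def test_scattered_isolated_label_low(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(150, 2))
        labels = np.where(rng.random(150) < 0.2, "rare", "common")
        batch = np.where(labels == "rare", "a", np.tile(["a", "b"], 75)[: 150])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = isolated_label_f1(_embedding(X), labels, batch, seed=0)
        assert score < 0.7

    def test_all_labels_in_all_batches_warns(self):
        rng = np.random.default_rng(6)
        X, types = _blobs(rng, [(0, 0), (30, 30)], 30)
        batch = np.tile(["a", "b"], 30)
        with pytest.warns(UserWarning, match="isolated"):
            isolated_label_f1(_embedding(X), types, batch, seed=0)


class TestNMI:
    def test_identical_partitions_one(self):
        assert nmi([0, 0, 1, 1], ["x", "x", "y", "y"]) == pytest.approx(1.0)

    def test_hand_computed_entropy_arithmetic(self):
        a = [0, 0, 1, 1]
        b = [0, 1, 1, 1]
        # independent computation from the definition
        def entropy(labels):
            _, counts = np.unique(labels, return_counts=True)
            p = counts / counts.sum()
            return -np.sum(p * np.log(p))

        joint = {(0, 0): 1, (0, 1): 1, (1, 1): 2}
        mi = 0.0
        for (x, y), c in joint.items():
            pxy = c / 4
            px = sum(v for k, v in joint.items() if k[0] == x) / 4
            py = sum(v for k, v in joint.items() if k[1] == y) / 4
            mi += pxy * np.log(pxy / (px * py))
        expected = mi / ((entropy(a) + entropy(b)) / 2)
        assert nmi(a, b) == pytest.approx(expected)

    def test_independent_partitions_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 4, size=5000)
        b = rng.integers(0, 4, size=5000)
        assert nmi(a, b) < 0.01


class TestSpeciesCenter:
    def test_single_species_identity(self):
        m = _cell_matrix(np.arange(12.0).reshape(3, 4))
        out = species_center(m, ["a"] * 4)
        assert np.allclose(out.dense(), m.dense())

    def test_constant_offset_removed_exactly(self):
        rng = np.random.default_rng(8)
        base = rng.normal(5, 1, size=(10, 40))
        X = base.copy()
        species = np.repeat(["a", "b"], 20)
        offset = rng.normal(0, 2, size=10)
        X[:, 20:] += offset[:, None]
        out = species_center(_cell_matrix(X, species=species), species).dense()
        means_a = out[:, :20].mean(axis=1)
        means_b = out[:, 20:].mean(axis=1)
        assert np.allclose(means_a, means_b, atol=1e-10)

    def test_absent_gene_untouched(self):
        X = np.array([[0.0, 0.0, 1.0, 2.0], [1.0, 1.0, 1.0, 1.0]])
        species = ["a", "a", "b", "b"]
        out = species_center(_cell_matrix(X, species=species), species).dense()
        assert np.allclose(out[0, :2], 0.0)  # gene absent in species a


class TestComposite:
    def test_weighted_total_machine_precision(self):
        comps = {name: 0.8 for name in SMS_COMPONENTS}
        comps.update({name: 0.6 for name in BCS_COMPONENTS})
        rep = composite_scores(comps)
        assert rep.species_mixing_score == pytest.approx(0.8, abs=1e-15)
        assert rep.bioconservation_score == pytest.approx(0.6, abs=1e-15)
        assert rep.total == 0.5 * rep.species_mixing_score + 0.5 * rep.bioconservation_score
        assert rep.total == pytest.approx(0.7, abs=1e-15)

    def test_all_ones(self):
        comps = {n: 1.0 for n in SMS_COMPONENTS + BCS_COMPONENTS}
        rep = composite_scores(comps)
        assert rep.species_mixing_score == rep.bioconservation_score == rep.total == 1.0

    def test_silhouette_rescaled(self):
        comps = {n: 1.0 for n in SMS_COMPONENTS}
        comps.update({"clisi_norm": 1.0, "isolated_label_f1": 1.0, "silhouette": 0.0})
        rep = composite_scores(comps)
        assert rep.components["silhouette_01"] == 0.5
        assert rep.bioconservation_score == pytest.approx((1 + 1 + 0.5) / 3)

    def test_missing_component_flagged_and_mean_over_present(self):
        comps = {n: 1.0 for n in SMS_COMPONENTS if n != "kbet"}
        comps.update({n: 1.0 for n in BCS_COMPONENTS})
        with pytest.warns(UserWarning, match="kbet"):
            rep = composite_scores(comps)
        assert rep.missing == ["kbet"]
        assert rep.species_mixing_score == 1.0

    def test_linearity_in_components(self):
        rng = np.random.default_rng(9)
        x = {n: float(rng.random()) for n in SMS_COMPONENTS + BCS_COMPONENTS}
        y = {n: float(rng.random()) for n in SMS_COMPONENTS + BCS_COMPONENTS}
        lam = 0.3
        mix = {n: lam * x[n] + (1 - lam) * y[n] for n in x}
        t_mix = composite_scores(mix).total
        t_lin = lam * composite_scores(x).total + (1 - lam) * composite_scores(y).total
        assert t_mix == pytest.approx(t_lin, abs=1e-12)


class TestMetricRangesFuzz:
    """Every component stays within its documented range on random inputs."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_ranges(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        X = rng.normal(size=(n, 4)) * rng.uniform(0.5, 3)
        e = _embedding(X)
        batch = rng.choice(["a", "b", "c"][: rng.integers(2, 4)], size=n)
        group = rng.choice(["t0", "t1", "t2"], size=n)
        cc = rng.random(n)
        idx = knn_indices(e, 10)
        adj = knn_adjacency(e, 10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert -1.0 <= silhouette_mean(e, group) <= 1.0
            assert 0.0 <= batch_asw(e, batch, group) <= 1.0
            assert 0.0 < graph_connectivity(adj, group) <= 1.0
            post = X + rng.normal(scale=0.1, size=X.shape)
            assert 0.0 <= pcr_comparison(X, post, batch) <= 1.0
            assert 0.0 <= cell_cycle_conservation(X, post, cc) <= 1.0
            assert 0.0 <= kbet_acceptance(idx, batch, seed=seed) <= 1.0
            raw = lisi(e, batch)
            assert np.all(raw >= 1.0 - 1e-9)
            assert np.all(raw <= len(np.unique(batch)) + 1e-9)
            assert 0.0 <= ilisi_norm(e, batch) <= 1.0
            assert 0.0 <= clisi_norm(e, group) <= 1.0
            assert 0.0 <= nmi(batch, group) <= 1.0
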