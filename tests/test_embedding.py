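import numpy as np
import pytest

from spacesvg.containers import ExpressionMatrix
from spacesvg.dependency import GeneClusters
from spacesvg.embedding import (
    aggregate,
    cluster_embedding,
    detect_domains,
    pooled_baseline,
    space_domains,
    spatial_smooth,
)
from spacesvg.geometry import SpotSet


@pytest.fixture(scope="module")
def grid_spots():
    g = np.linspace(0, 1, 15)
    gx, gy = np.meshgrid(g, g)
    coords = np.column_stack([gx.ravel(), gy.ravel()])
    return SpotSet(tuple(f"s{i}" for i in range(coords.shape[0])), coords)


@pytest.fixture(scope="module")
def two_domain_data(grid_spots):
    """Two half-plane domains with 12 marker genes each."""
    gen = np.random.default_rng(99)
    n = grid_spots.n_spots
    left = (grid_spots.coords[:, 0] < 0.5).astype(float)
    z = (left - left.mean()) / left.std()
    Y = np.vstack(
        [2.0 * z + gen.normal(size=n) for _ in range(12)]
        + [-1.5 * z + gen.normal(size=n) for _ in range(12)]
    )
    expr = ExpressionMatrix(tuple(f"g{i}" for i in range(24)), grid_spots.spot_ids, Y)
    truth = (left > 0).astype(int)
    return expr, truth


class TestSpatialSmooth:
    def test_tiny_bandwidth_is_identity(self, grid_spots, rng):
        x = rng.normal(size=(3, grid_spots.n_spots))
        out = spatial_smooth(x, grid_spots, bandwidth=1e-4)
        np.testing.assert_allclose(out, x, atol=1e-8)

    def test_constant_gene_unchanged(self, grid_spots):
        x = np.full((1, grid_spots.n_spots), 3.7)
        out = spatial_smooth(x, grid_spots, bandwidth=0.2)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_step_function_softened_but_means_kept(self):
        # 1-D arrangement: step at the middle
        coords = np.linspace(0, 1, 60)[:, None]
        spots = SpotSet(tuple(range(60)), coords)
        x = np.where(coords.ravel() < 0.5, 0.0, 1.0)[None, :]
        out = spatial_smooth(x, spots, bandwidth=0.05)
        # brute-force weighted average oracle at one interior spot
        w = np.exp(-((coords.ravel() - coords[10, 0]) ** 2) / (2 * 0.05 ** 2))
        oracle = float(w @ x[0] / w.sum())
        assert out[0, 10] == pytest.approx(oracle, abs=1e-12)
        assert out[0, 5] == pytest.approx(0.0, abs=1e-3)
        assert out[0, 55] == pytest.approx(1.0, abs=1e-3)
        assert 0.2 < out[0, 30] < 0.8

    def test_invalid_bandwidth(self, grid_spots):
        with pytest.raises(ValueError):
            spatial_smooth(np.zeros((1, grid_spots.n_spots)), grid_spots, bandwidth=0.0)


class TestClusterEmbedding:
    def test_two_gene_cluster_rank_bound(self, grid_spots, rng):
        E = cluster_embedding(rng.normal(size=(2, grid_spots.n_spots)), grid_spots)
        assert E.shape == (grid_spots.n_spots, 1)

    def test_duplicated_gene_rank_one(self, grid_spots, rng):
        base = rng.normal(size=grid_spots.n_spots)
        block = np.tile(base, (10, 1))
        E = cluster_embedding(block, grid_spots, d=5)
        var = E.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_gene_order_invariance_up_to_sign(self, grid_spots, rng):
        block = rng.normal(size=(8, grid_spots.n_spots))
        E1 = cluster_embedding(block, grid_spots, d=3)
        E2 = cluster_embedding(block[::-1], grid_spots, d=3)
        for k in range(3):
            agree = np.allclose(E1[:, k], E2[:, k], atol=1e-8)
            flipped = np.allclose(E1[:, k], -E2[:, k], atol=1e-8)
            assert agree or flipped

    def test_first_column_separates_two_domains(self, grid_spots, two_domain_data):
        expr, truth = two_domain_data
        E = cluster_embedding(expr.values[:12], grid_spots, d=2)
        from sklearn.cluster import KMeans
        from spacesvg.metrics import adjusted_rand_index

        labels = KMeans(2, n_init=10, random_state=0).fit(E[:, :1]).labels_
        assert adjusted_rand_index(truth, labels) == 1.0


class TestAggregate:
    def test_single_block_identity(self, rng):
        b = rng.normal(size=(30, 4))
        np.testing.assert_array_equal(aggregate([b]), b)

    def test_column_counts_add_up(self, rng):
        blocks = [rng.normal(size=(30, 20)) for _ in range(3)]
        assert aggregate(blocks).shape == (30, 60)

    def test_mismatched_spots_rejected(self, rng):
        with pytest.raises(ValueError):
            aggregate([rng.normal(size=(30, 2)), rng.normal(size=(29, 2))])


class TestDetectDomains:
    def test_separated_clouds_recovered_by_walktrap(self, rng):
        a = rng.normal(size=(40, 3)) * 0.1
        b = rng.normal(size=(40, 3)) * 0.1 + 5.0
        E = np.vstack([a, b])
        labels = detect_domains(E, method="walktrap", k_domains=2, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:40])) == 1
        assert len(np.unique(labels[40:])) == 1

    def test_single_domain_request(self, rng):
        E = rng.normal(size=(25, 2))
        labels = detect_domains(E, k_domains=1)
        assert np.all(labels == 0)

    def test_deterministic(self, rng):
        E = rng.normal(size=(60, 4))
        l1 = detect_domains(E, method="leiden", seed=5)
        l2 = detect_domains(E, method="leiden", seed=5)
        np.testing.assert_array_equal(l1, l2)

    def test_column_sign_invariance(self, rng):
        E = rng.normal(size=(60, 4))
        flip = E * np.array([1, -1, 1, -1])
        l1 = detect_domains(E, method="walktrap", k_domains=3, seed=0)
        l2 = detect_domains(flip, method="walktrap", k_domains=3, seed=0)
        from spacesvg.metrics import adjusted_rand_index

        assert adjusted_rand_index(l1, l2) == 1.0

    def test_invalid_arguments(self, rng):
        E = rng.normal(size=(20, 2))
        with pytest.raises(ValueError):
            detect_domains(E, k_domains=50)
        with pytest.raises(ValueError):
            detect_domains(E, method="dbscan")


class TestSpaceDomainsAndBaseline:
    def test_two_domain_recovery(self, grid_spots, two_domain_data):
        from spacesvg.metrics import adjusted_rand_index

        expr, truth = two_domain_data
        clusters = GeneClusters(
            {g: (0 if i < 12 else 1) for i, g in enumerate(expr.gene_ids)}, (), 2
        )
        # denser SNN graph: at 225 spots a 10-NN graph is chain-like
        # along the smoothed gradient and walktrap can cut off-boundary
        labels, E = space_domains(
            expr, grid_spots, clusters, method="walktrap", k_domains=2, knn=20, seed=0
        )
        assert adjusted_rand_index(truth, labels) == pytest.approx(1.0)
        assert E.shape[0] == grid_spots.n_spots

    def test_block_order_invariance(self, grid_spots, two_domain_data):
        from spacesvg.metrics import adjusted_rand_index

        expr, _ = two_domain_data
        c1 = GeneClusters({g: (0 if i < 12 else 1) for i, g in enumerate(expr.gene_ids)}, (), 2)
        c2 = GeneClusters({g: (1 if i < 12 else 0) for i, g in enumerate(expr.gene_ids)}, (), 2)
        l1, _ = space_domains(expr, grid_spots, c1, method="walktrap", k_domains=2, seed=0)
        l2, _ = space_domains(expr, grid_spots, c2, method="walktrap", k_domains=2, seed=0)
        assert adjusted_rand_index(l1, l2) == 1.0

    def test_baseline_reduces_to_single_cluster_path(self, grid_spots, two_domain_data):
        """With one gene cluster covering all SVGs the two paths agree."""
        import pandas as pd

        from spacesvg.detection import SVGTestResult
        from spacesvg.metrics import adjusted_rand_index

        expr, truth = two_domain_data
        table = pd.DataFrame(
            {
                "gene_id": list(expr.gene_ids),
                "p_combined": np.linspace(1e-10, 1e-8, expr.n_genes),
                "q_value": np.full(expr.n_genes, 1e-8),
                "is_svg": True,
            }
        )
        svg_res = SVGTestResult(table, alpha=0.05)
        clusters = GeneClusters({g: 0 for g in expr.gene_ids}, (), 1)
        l_space, _ = space_domains(
            expr, grid_spots, clusters, method="walktrap", k_domains=2, seed=0
        )
        l_base, _ = pooled_baseline(
            expr, grid_spots, svg_res, n_top=expr.n_genes, method="walktrap",
            k_domains=2, seed=0,
        )
        assert adjusted_rand_index(l_space, l_base) == 1.0

    def test_baseline_dimension_truncated_by_rank(self, grid_spots, two_domain_data):
        import pandas as pd

        from spacesvg.detection import SVGTestResult

        expr, _ = two_domain_data
        table = pd.DataFrame(
            {
                "gene_id": list(expr.gene_ids),
                "p_combined": np.linspace(1e-10, 1e-8, expr.n_genes),
                "q_value": np.full(expr.n_genes, 1e-8),
                "is_svg": True,
            }
        )
        svg_res = SVGTestResult(table, alpha=0.05)
        _, E = pooled_baseline(
            expr, grid_spots, svg_res, n_top=5, d=20, method="walktrap", k_domains=2
        )
        assert E.shape[1] == 4  # five genes -> rank bound 4
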