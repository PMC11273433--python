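import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

from hemograph.graphs import (
    RegionGraph,
    SuperpixelSegmentation,
    build_region_graph,
    degree_matrix,
    eigendecompose,
    graph_fourier,
    inverse_graph_fourier,
    laplacian,
    load_graph,
    pad_graph,
    region_adjacency,
    region_features,
    save_graph,
    scale_laplacian,
    segment_superpixels,
    spectral_filter,
)
from tests.conftest import random_adjacency

PATH3 = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 1.0, 0.0]])


def seg_from_label_map(lm):
    lm = np.asarray(lm)
    n = lm.max() + 1
    sizes = np.bincount(lm.ravel(), minlength=n)
    rows, cols = np.indices(lm.shape)
    cent = np.stack(
        [
            np.bincount(lm.ravel(), weights=rows.ravel(), minlength=n) / sizes,
            np.bincount(lm.ravel(), weights=cols.ravel(), minlength=n) / sizes,
        ],
        axis=1,
    )
    return SuperpixelSegmentation(lm, n, sizes, cent)


class TestSegmentation:
    def test_constant_image_gives_near_equal_tiles(self):
        seg = segment_superpixels(np.full((64, 64), 0.5), 4)
        assert seg.n_regions == 4
        assert seg.region_sizes.sum() == 64 * 64
        assert seg.region_sizes.min() >= 0.8 * seg.region_sizes.mean()

    def test_label_map_is_a_partition(self, rng):
        img = rng.random((64, 64))
        seg = segment_superpixels(img, 20)
        assert seg.label_map.shape == img.shape
        labels = np.unique(seg.label_map)
        assert np.array_equal(labels, np.arange(seg.n_regions))
        assert np.all(seg.region_sizes >= 1)
        assert seg.region_sizes.sum() == img.size

    def test_homogeneous_halves_yield_pure_regions(self):
        img = np.zeros((64, 128))
        img[:, 64:] = 1.0
        seg = segment_superpixels(img, 2)
        assert seg.n_regions == 2
        for r in range(2):
            vals = img[seg.label_map == r]
            purity = max((vals == 0).mean(), (vals == 1).mean())
            assert purity >= 0.95

    def test_too_many_regions_rejected(self):
        with pytest.raises(ValueError):
            segment_superpixels(np.zeros((8, 8)), 100)


class TestRegionFeatures:
    def test_constant_image(self):
        seg = seg_from_label_map([[0, 0], [1, 1]])
        X = region_features(np.full((2, 2), 0.7), seg)
        assert np.allclose(X, 0.7)

    def test_two_region_contrast(self):
        seg = seg_from_label_map([[0, 1], [0, 1]])
        img = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert np.allclose(region_features(img, seg)[:, 0], [0.0, 1.0])

    def test_matches_per_region_loop(self, rng):
        lm = rng.integers(0, 5, size=(10, 10))
        while len(np.unique(lm)) < 5:
            lm = rng.integers(0, 5, size=(10, 10))
        img = rng.random((10, 10))
        X = region_features(img, seg_from_label_map(lm))
        for r in range(5):
            assert X[r, 0] == pytest.approx(img[lm == r].mean())

    def test_shape_mismatch_rejected(self):
        seg = seg_from_label_map([[0, 1]])
        with pytest.raises(ValueError):
            region_features(np.zeros((3, 3)), seg)


class TestRegionAdjacency:
    def test_four_single_pixel_regions_form_k4(self):
        # 8-connectivity makes diagonal pixels adjacent too
        seg = seg_from_label_map([[0, 1], [2, 3]])
        W = region_adjacency(seg)
        assert np.array_equal(W, np.ones((4, 4)) - np.eye(4))

    def test_left_right_halves(self):
        lm = np.zeros((4, 4), dtype=int)
        lm[:, 2:] = 1
        W = region_adjacency(seg_from_label_map(lm))
        assert np.array_equal(W, [[0, 1], [1, 0]])

    def test_three_stripes_form_path(self):
        lm = np.zeros((3, 9), dtype=int)
        lm[:, 3:6] = 1
        lm[:, 6:] = 2
        W = region_adjacency(seg_from_label_map(lm))
        assert np.array_equal(W, PATH3)

    def test_gaussian_weights_on_contiguous_pairs(self):
        lm = np.zeros((4, 4), dtype=int)
        lm[:, 2:] = 1
        seg = seg_from_label_map(lm)
        W = region_adjacency(seg, gaussian_sigma=2.0)
        d = np.linalg.norm(seg.region_centroids[0] - seg.region_centroids[1])
        assert W[0, 1] == pytest.approx(np.exp(-(d**2) / 8.0))


class TestSpectralCore:
    def test_degree_of_path_graph(self):
        assert np.array_equal(degree_matrix(PATH3), np.diag([1.0, 2.0, 1.0]))

    def test_degree_of_empty_graph(self):
        assert np.array_equal(degree_matrix(np.zeros((4, 4))), np.zeros((4, 4)))

    def test_degree_matches_row_sums(self, rng):
        W = random_adjacency(rng, 8)
        assert np.allclose(np.diag(degree_matrix(W)), W.sum(axis=1))

    def test_nonsquare_rejected(self):
        with pytest.raises(ValueError):
            degree_matrix(np.zeros((2, 3)))

    def test_path_graph_laplacian_textbook_values(self):
        L = laplacian(PATH3)
        assert np.array_equal(L, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_laplacian_annihilates_constants(self, rng):
        L = laplacian(random_adjacency(rng, 7))
        assert np.allclose(L @ np.ones(7), 0.0)

    def test_laplacian_quadratic_form(self, rng):
        W = random_adjacency(rng, 6)
        L = laplacian(W)
        x = rng.normal(size=6)
        expected = 0.5 * sum(
            W[i, j] * (x[i] - x[j]) ** 2 for i in range(6) for j in range(6)
        )
        assert x @ L @ x == pytest.approx(expected)

    def test_path_graph_eigenvalues(self):
        _, lam, lam_max = eigendecompose(laplacian(PATH3))
        assert np.allclose(lam, [0.0, 1.0, 3.0], atol=1e-10)
        assert lam_max == pytest.approx(3.0)

    def test_complete_graph_eigenvalues(self):
        n = 5
        W = np.ones((n, n)) - np.eye(n)
        _, lam, _ = eigendecompose(laplacian(W))
        assert np.allclose(lam, [0.0] + [float(n)] * (n - 1), atol=1e-10)

    def test_reconstruction_and_orthonormality(self, rng):
        L = laplacian(random_adjacency(rng, 9))
        U, lam, _ = eigendecompose(L)
        assert np.allclose(U.T @ U, np.eye(9), atol=1e-8)
        assert np.allclose(U @ np.diag(lam) @ U.T, L, atol=1e-8)

    def test_edgeless_laplacian_ok(self):
        U, lam, _ = eigendecompose(np.zeros((4, 4)))
        assert np.allclose(lam, 0.0)
        assert np.allclose(U @ np.diag(lam) @ U.T, np.zeros((4, 4)))

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            eigendecompose(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_zero_eigenvalue_count_equals_components(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 10))
            W = random_adjacency(rng, n, p=0.25)
            n_comp, _ = connected_components(W, directed=False)
            _, lam, _ = eigendecompose(laplacian(W))
            assert int(np.sum(np.abs(lam) < 1e-8)) == n_comp


class TestGraphFourier:
    def test_eigenvector_maps_to_basis_vector(self, rng):
        L = laplacian(random_adjacency(rng, 6))
        U, _, _ = eigendecompose(L)
        q_hat = graph_fourier(U[:, 0], U)
        assert np.allclose(q_hat, np.eye(6)[0], atol=1e-10)

    def test_roundtrip_and_parseval(self, rng):
        L = laplacian(random_adjacency(rng, 8))
        U, _, _ = eigendecompose(L)
        q = rng.normal(size=8)
        q_hat = graph_fourier(q, U)
        assert np.allclose(inverse_graph_fourier(q_hat, U), q, atol=1e-10)
        assert np.linalg.norm(q_hat) == pytest.approx(np.linalg.norm(q))

    def test_length_mismatch_rejected(self, rng):
        U = np.eye(4)
        with pytest.raises(ValueError):
            graph_fourier(np.zeros(5), U)


class TestSpectralFilter:
    def test_identity_filter(self, rng):
        L = laplacian(random_adjacency(rng, 6))
        U, lam, _ = eigendecompose(L)
        x = rng.normal(size=(6, 2))
        assert np.allclose(spectral_filter(x, lambda l: np.ones_like(l), U, lam), x)

    def test_lambda_filter_applies_laplacian(self, rng):
        L = laplacian(random_adjacency(rng, 6))
        U, lam, _ = eigendecompose(L)
        x = rng.normal(size=6)
        assert np.allclose(spectral_filter(x, lambda l: l, U, lam), L @ x, atol=1e-9)

    def test_lambda_squared_is_double_application(self, rng):
        L = laplacian(random_adjacency(rng, 6))
        U, lam, _ = eigendecompose(L)
        x = rng.normal(size=6)
        y = spectral_filter(x, lambda l: l**2, U, lam)
        assert np.allclose(y, L @ (L @ x), atol=1e-8)

    def test_polynomial_filter_equals_matrix_polynomial(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 13))
            L = laplacian(random_adjacency(rng, n))
            U, lam, _ = eigendecompose(L)
            coeffs = rng.normal(size=3)
            x = rng.normal(size=n)
            y = spectral_filter(
                x, lambda l: coeffs[0] + coeffs[1] * l + coeffs[2] * l**2, U, lam
            )
            M = coeffs[0] * np.eye(n) + coeffs[1] * L + coeffs[2] * L @ L
            assert np.allclose(y, M @ x, atol=1e-8)

    def test_nonfinite_filter_rejected(self, rng):
        L = laplacian(random_adjacency(rng, 4))
        U, lam, _ = eigendecompose(L)
        with pytest.raises(ValueError):
            spectral_filter(np.ones(4), lambda l: np.full_like(l, np.nan), U, lam)


class TestScaleLaplacian:
    def test_two_point_spectrum_maps_to_unit_interval(self):
        L = np.diag([0.0, 2.0])
        Lt = scale_laplacian(L, 2.0)
        assert np.allclose(np.linalg.eigvalsh(Lt), [-1.0, 1.0])

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            scale_laplacian(np.zeros((3, 3)), 0.0)

    def test_spectrum_lands_in_unit_interval(self, rng):
        L = laplacian(random_adjacency(rng, 8))
        _, lam, lam_max = eigendecompose(L)
        lt = np.linalg.eigvalsh(scale_laplacian(L, lam_max))
        assert lt.min() >= -1.0 - 1e-10 and lt.max() <= 1.0 + 1e-10


class TestPadGraph:
    def test_already_at_budget_keeps_everything(self, graph_factory, rng):
        g = graph_factory(rng, 5)
        p = pad_graph(g, 5)
        assert np.array_equal(p.W, g.W)
        assert p.mask.all()

    def test_padded_nodes_are_isolated(self, graph_factory, rng):
        g = graph_factory(rng, 3)
        p = pad_graph(g, 5)
        assert p.n_nodes == 5
        assert np.allclose(p.W[3:, :], 0.0)
        assert np.allclose(p.L[3:, 3:], 0.0)
        assert list(p.mask) == [True] * 3 + [False] * 2

    def test_over_budget_rejected(self, graph_factory, rng):
        g = graph_factory(rng, 6)
        with pytest.raises(ValueError):
            pad_graph(g, 5)

    def test_spectral_filter_on_real_block_unchanged(self, graph_factory, rng):
        """Padding adds a zero Laplacian block; a filter with g(0) = 0 leaves
        the real nodes' filtered signal untouched."""
        g = graph_factory(rng, 6)
        p = pad_graph(g, 9)
        U, lam, _ = eigendecompose(g.L)
        Up, lamp, _ = eigendecompose(p.L)
        x = rng.normal(size=6)
        xp = np.r_[x, np.zeros(3)]
        y = spectral_filter(x, lambda l: l + 0.5 * l**2, U, lam)
        yp = spectral_filter(xp, lambda l: l + 0.5 * l**2, Up, lamp)
        assert np.allclose(yp[:6], y, atol=1e-8)
        assert np.allclose(yp[6:], 0.0, atol=1e-10)


class TestBuiltGraphInvariants:
    def test_region_graphs_satisfy_spectral_invariants(self, rng):
        img = rng.random((64, 64))
        g = build_region_graph(img, 15)
        assert np.array_equal(g.W, g.W.T)
        assert np.allclose(np.diag(g.W), 0.0)
        assert np.all(g.W >= 0)
        assert np.allclose(g.L.sum(axis=1), 0.0, atol=1e-9)
        assert np.linalg.eigvalsh(g.L).min() >= -1e-8

    def test_save_load_roundtrip(self, tmp_path, rng):
        img = rng.random((64, 64))
        g = build_region_graph(img, 10, label="ALL", source_id="x")
        save_graph(g, tmp_path / "g.npz", {"n_regions": 10})
        h = load_graph(tmp_path / "g.npz")
        assert np.allclose(h.W, g.W)
        assert np.allclose(h.X, g.X)
        assert h.label == "ALL" and h.source_id == "x"
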