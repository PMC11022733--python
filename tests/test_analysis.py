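"""Image properties, spatial grids, retinotopy, and aRF estimation."""

import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

import v1enc as v
from v1enc.analysis import SpatialGrid

from oracles import distance_curve_brute


# ---------------------------------------------------------------------------
# image properties
# ---------------------------------------------------------------------------

class TestImageProperties:
    def test_flat_image(self):
        p = v.image_properties(np.full((10, 12), 42.0))
        assert (p.brightness, p.contrast, p.complexity) == (42.0, 0.0, 0.0)

    def test_checkerboard_brightness_and_contrast(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 255.0
        p = v.image_properties(img)
        assert p.brightness == pytest.approx(127.5)
        assert p.contrast == pytest.approx(127.5)

    def test_step_edge_matches_direct_sobel_convolution(self):
        """Hand convolution of the 3x3 Sobel pair with reflect padding on a
        6x6 vertical step edge."""
        img = np.zeros((6, 6))
        img[:, 3:] = 10.0

        kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
        ky = kx.T
        pad = np.pad(img, 1, mode="reflect")
        sv = np.zeros_like(img)
        sh = np.zeros_like(img)
        for i in range(6):
            for j in range(6):
                win = pad[i : i + 3, j : j + 3]
                sv[i, j] = (win * kx).sum()
                sh[i, j] = (win * ky).sum()
        want = float(np.sqrt(sv**2 + sh**2).mean())
        assert v.image_properties(img).complexity == pytest.approx(want, rel=1e-12)
        assert want > 0

    def test_transpose_leaves_complexity_unchanged(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (12, 17))
        a = v.image_properties(img)
        b = v.image_properties(img.T)
        assert a.complexity == pytest.approx(b.complexity, rel=1e-12)

    def test_constant_shift_changes_brightness_only(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 200, (9, 9))
        a = v.image_properties(img)
        b = v.image_properties(img + 17.0)
        assert b.brightness == pytest.approx(a.brightness + 17.0)
        assert b.contrast == pytest.approx(a.contrast, rel=1e-12)
        assert b.complexity == pytest.approx(a.complexity, rel=1e-12)


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def _grid_axes(shape, z_span):
    x = np.linspace(-1, 1, shape[0])
    y = np.linspace(-1, 1, shape[1])
    z = np.linspace(0.0, z_span, shape[2])
    return x, y, z, np.meshgrid(x, y, z, indexing="ij")


def gradient_field(shape=(25, 25, 10), K=20, length=0.6, seed=0, z_span=0.135):
    """Smooth field drifting along one spatial gradient: each cell's K-vector
    is a bank of Gaussian bumps of the scalar drift coordinate, so similarity
    falls off monotonically along the gradient (the regime the rank-distance
    curve is designed for)."""
    rng = np.random.default_rng(seed)
    x, y, z, (gx, gy, gz) = _grid_axes(shape, z_span)
    t = (gx + gy) / 2 + gz
    anchors = rng.uniform(t.min(), t.max(), K)
    vals = np.exp(-((t[..., None] - anchors) ** 2) / (2 * length**2))
    return SpatialGrid(values=vals, x=x, y=y, z=z)


def bump_field(shape=(25, 25, 10), K=60, length=0.5, seed=6, z_span=0.135):
    """Isotropically smooth field: K Gaussian bumps at random 3-D anchors, so
    cell similarity decays with 3-D separation in every direction."""
    rng = np.random.default_rng(seed)
    x, y, z, (gx, gy, gz) = _grid_axes(shape, z_span)
    pts = np.stack([gx, gy, gz], axis=-1)
    anchors = rng.uniform(-1, 1, (K, 3)) * [1, 1, z_span]
    d2 = ((pts[..., None, :] - anchors) ** 2).sum(axis=-1)
    return SpatialGrid(values=np.exp(-d2 / (2 * length**2)), x=x, y=y, z=z)


class TestGridNeurons:
    def test_default_cell_count(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(-1, 1, (40, 3))
        grid = v.grid_neurons(coords, rng.normal(size=(40, 5)))
        assert grid.n_cells == 6250
        assert grid.shape == (25, 25, 10)
        assert np.allclose(grid.x, np.linspace(-1, 1, 25))

    def test_exact_at_a_neuron_location(self):
        # neuron 0 sits exactly on grid node (2, 2, 0) of a 5x5x2 grid
        coords = np.array(
            [[0.0, 0.0, 0.0]]
            + [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-0.5, 1.0)]
        )
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(len(coords), 4))
        grid = v.grid_neurons(coords, vals, shape=(5, 5, 2), z_range=(0.0, 1.0))
        assert np.allclose(grid.values[2, 2, 0], vals[0], atol=1e-9)

    def test_outside_hull_is_missing(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-0.3, 0.3, (30, 3))  # centered cloud
        grid = v.grid_neurons(coords, rng.normal(size=(30, 2)))
        assert grid.missing_mask()[0, 0, 0]  # corner cell far outside the hull
        assert not grid.missing_mask().all()

    def test_values_within_input_range(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(-1, 1, (60, 3))
        vals = rng.normal(size=(60, 3))
        grid = v.grid_neurons(coords, vals)
        for k in range(3):
            col = grid.values[..., k]
            good = ~np.isnan(col)
            assert col[good].min() >= vals[:, k].min() - 1e-9
            assert col[good].max() <= vals[:, k].max() + 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            v.grid_neurons(np.zeros((3, 3)), np.zeros((3, 1)))


class TestDistanceSimilarity:
    def test_identical_vectors_give_unit_curve(self):
        vec = np.array([1.0, 2.0, 5.0])
        grid = SpatialGrid(
            values=np.broadcast_to(vec, (3, 3, 2, 3)).copy(),
            x=np.linspace(-1, 1, 3), y=np.linspace(-1, 1, 3), z=np.array([0.0, 0.1]),
        )
        curve = v.distance_similarity_curve(grid)
        assert all(val == pytest.approx(1.0) for _, val in curve)

    def test_self_similarity_at_zero_offset(self):
        grid = gradient_field(shape=(5, 5, 2), K=6, seed=1)
        curve = v.distance_similarity_curve(grid)
        assert curve[0][0] == 0
        assert curve[0][1] == pytest.approx(1.0)

    def test_matches_brute_force_on_small_grid(self):
        grid = bump_field(shape=(5, 5, 2), K=6, seed=2)
        # knock out a few cells to exercise the missing-cell path
        grid.values[0, 1, 0] = np.nan
        grid.values[3, 2, 1] = np.nan
        curve = v.distance_similarity_curve(grid)
        keep = ~grid.missing_mask().ravel()
        cells = [tuple(c) for c in grid.cell_coordinates()[keep]]
        vecs = grid.values.reshape(-1, 6)[keep].tolist()
        want = distance_curve_brute(cells, vecs)
        assert len(curve) == len(want)
        for (k1, v1), (k2, v2) in zip(curve, want):
            assert k1 == k2
            assert v1 == pytest.approx(v2, abs=1e-10)

    def test_smooth_field_similarity_decays_with_distance(self):
        grid = gradient_field(seed=3)
        curve = v.distance_similarity_curve(grid)
        assert v.curve_distance_correlation(curve) < -0.9

    def test_binned_variant_decays_for_isotropic_field(self):
        """The Euclidean-binned pairwise curve handles the isotropic case the
        rank-distance curve cannot: similarity falls with true pair
        distance regardless of direction."""
        grid = bump_field(seed=9)
        curve = v.binned_distance_similarity(grid, n_bins=15)
        s = np.array([c[1] for c in curve])
        assert s[0] > 0.8  # nearest pairs are nearly identical
        half = len(s) // 2
        assert np.all(np.diff(s[:half]) < 0)  # monotone decay over the near range
        assert s[half] < 0.3

    def test_binned_variant_brute_force_small(self):
        grid = bump_field(shape=(3, 3, 2), K=4, seed=10)
        curve = v.binned_distance_similarity(grid, n_bins=4)
        vals = grid.values.reshape(-1, 4)
        coords = grid.cell_coordinates()
        C = np.corrcoef(vals)
        pairs = []
        n = len(vals)
        for i in range(n):
            for j in range(i + 1, n):
                pairs.append((np.linalg.norm(coords[i] - coords[j]), C[i, j]))
        d = np.array([p[0] for p in pairs])
        c = np.array([p[1] for p in pairs])
        edges = np.linspace(0, d.max() + 1e-12, 5)
        want = [
            ((lo + hi) / 2, c[(d >= lo) & (d < hi)].mean())
            for lo, hi in zip(edges[:-1], edges[1:])
            if ((d >= lo) & (d < hi)).any()
        ]
        assert len(curve) == len(want)
        for (da, sa), (db, sb) in zip(curve, want):
            assert da == pytest.approx(db, abs=1e-12)
            assert sa == pytest.approx(sb, abs=1e-10)

    def test_across_grids_on_identical_fields_matches_within(self):
        grid = gradient_field(shape=(5, 5, 2), K=6, seed=4)
        within = v.distance_similarity_curve(grid)
        across = v.distance_similarity_curve(grid, grid)
        for (_, a), (_, b) in zip(within, across):
            assert a == pytest.approx(b, abs=1e-10)


class TestReferenceMap:
    def test_projection_shape_per_plane(self):
        grid = bump_field(shape=(25, 25, 10), K=8, seed=5)
        assert v.reference_correlation_map(grid, (12, 12, 5), "XY").shape == (25, 25)
        assert v.reference_correlation_map(grid, (12, 12, 5), "XZ").shape == (25, 10)
        assert v.reference_correlation_map(grid, (12, 12, 5), "YZ").shape == (25, 10)

    def test_decays_with_distance_from_reference(self):
        grid = bump_field(seed=6)
        ref = (12, 12, 5)
        cmap = v.reference_correlation_map(grid, ref, "XY")
        xi, yi = np.meshgrid(np.arange(25), np.arange(25), indexing="ij")
        dist = np.sqrt((xi - ref[0]) ** 2 + (yi - ref[1]) ** 2).ravel()
        rho = spearmanr(cmap.ravel(), dist).statistic
        assert rho < -0.8
        assert cmap[ref[0], ref[1]] == max(cmap.ravel())

    def test_missing_reference_rejected(self):
        grid = bump_field(shape=(5, 5, 2), K=4, seed=7)
        grid.values[1, 1, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            v.reference_correlation_map(grid, (1, 1, 1))


# ---------------------------------------------------------------------------
# retinotopy
# ---------------------------------------------------------------------------

class TestRetinotopy:
    def test_singleton_ensemble_equals_model_mu(self, ensemble_run):
        dataset, _, models, _ = ensemble_run
        df = v.retinotopic_map(models[:1], dataset.subject_id)
        mu = models[0].readouts[dataset.subject_id].positions_mu()
        assert np.allclose(df[["mu_x", "mu_y"]].to_numpy(), mu, atol=1e-7)
        assert np.all(np.abs(df[["mu_x", "mu_y"]].to_numpy()) < 1)

    def test_ensemble_average_recovers_retinotopy(self, recovery_run):
        dataset, truth, model, _ = recovery_run
        df = v.retinotopic_map([model], dataset.subject_id)
        r = pearsonr(df["coord_x"], df["mu_x"]).statistic
        assert r >= 0.8

    def test_unknown_subject(self, ensemble_run):
        _, _, models, _ = ensemble_run
        with pytest.raises(KeyError):
            v.retinotopic_map(models, "missing-subject")


# ---------------------------------------------------------------------------
# artificial receptive fields
# ---------------------------------------------------------------------------

def linear_gaussian_stub(shape=(36, 64), center=(40.0, 18.0), sigma=5.0, gain=3.0):
    """LN stub neuron: Gaussian RF inner product -> ELU + 1."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    rf = np.exp(-(((xs - center[0]) ** 2) + (ys - center[1]) ** 2) / (2 * sigma**2))
    rf /= np.linalg.norm(rf)

    def predict(noise):
        drive = gain * noise.reshape(len(noise), -1) @ rf.ravel()
        return np.where(drive > 0, drive + 1.0, np.exp(np.minimum(drive, 0)))[:, None]

    return rf, predict


class TestEstimateArf:
    def test_constant_predictor_map_shrinks_with_n(self):
        fn = lambda x: np.ones((len(x), 1))
        small = v.estimate_arf(fn, (16, 16), n_images=200, rng=np.random.default_rng(0))
        large = v.estimate_arf(fn, (16, 16), n_images=20000, rng=np.random.default_rng(0))
        assert large.std() < small.std()
        assert large.std() < 0.02

    def test_stub_neuron_recovery(self):
        rf, predict = linear_gaussian_stub()
        maps = v.estimate_arf(predict, (36, 64), n_images=30000, rng=np.random.default_rng(1))
        r = pearsonr(maps[0].ravel(), rf.ravel()).statistic
        assert r >= 0.8

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            v.estimate_arf(lambda x: np.ones((len(x), 1)), (8, 8), n_images=0)


class TestGaussianFit:
    def test_exact_gaussian_recovered(self):
        ys, xs = np.mgrid[0:50, 0:60].astype(float)
        true = dict(amp=2.0, cx=33.0, cy=21.0, sx=6.0, sy=3.5, off=0.3)
        img = true["amp"] * np.exp(
            -0.5 * (((xs - true["cx"]) / true["sx"]) ** 2 + ((ys - true["cy"]) / true["sy"]) ** 2)
        ) + true["off"]
        fit = v.fit_gaussian_2d(img)
        assert fit.success
        assert fit.center_x == pytest.approx(true["cx"], abs=1e-4)
        assert fit.center_y == pytest.approx(true["cy"], abs=1e-4)
        assert fit.amplitude == pytest.approx(true["amp"], rel=1e-4)
        assert fit.offset == pytest.approx(true["off"], abs=1e-5)

    def test_noisy_gaussian_center_within_one_pixel(self):
        rng = np.random.default_rng(2)
        ys, xs = np.mgrid[0:40, 0:40].astype(float)
        img = np.exp(-0.5 * (((xs - 17.3) / 4) ** 2 + ((ys - 22.8) / 4) ** 2))
        img += rng.normal(0, 0.05, img.shape)
        fit = v.fit_gaussian_2d(img)
        assert abs(fit.center_x - 17.3) < 1.0
        assert abs(fit.center_y - 22.8) < 1.0

    def test_center_bounded_to_image(self):
        rng = np.random.default_rng(3)
        fit = v.fit_gaussian_2d(rng.normal(size=(144, 256)))
        assert 0 <= fit.center_x < 256
        assert 0 <= fit.center_y < 144

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            v.fit_gaussian_2d(np.ones((10, 10)))
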