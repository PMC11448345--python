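"""Structure-tensor orientation and coherency: conventions, oracles, recovery."""

import numpy as np
import pytest
from skimage.transform import rotate

from rfmirsi.exceptions import UndefinedOrientationError
from rfmirsi.morphometrics import (
    coherency,
    dominant_orientation,
    roi_metrics,
    structure_tensor,
    tile_rois,
)
from rfmirsi.phantom import PhantomSpec, render_fibers
from rfmirsi.validation import angular_difference
from conftest import grating


def naive_structure_tensor(roi, grad_sigma=1.0):
    """Double-loop re-computation: explicit kernels, explicit averaging."""
    from scipy import ndimage

    # effective Gaussian-derivative kernels via a centered impulse response
    radius = int(4 * grad_sigma + 0.5) + 1
    size = 2 * radius + 1
    impulse = np.zeros((size, size))
    impulse[radius, radius] = 1.0
    k_r = ndimage.gaussian_filter(impulse, grad_sigma, order=(1, 0))
    k_c = ndimage.gaussian_filter(impulse, grad_sigma, order=(0, 1))
    padded = np.pad(roi, radius, mode="edge")
    h, w = roi.shape
    gr = np.zeros((h, w))
    gc = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            patch = padded[r : r + size, c : c + size]
            # convolution with the impulse response == the filter output
            gr[r, c] = np.sum(patch * k_r[::-1, ::-1])
            gc[r, c] = np.sum(patch * k_c[::-1, ::-1])
    gx, gy = gc, -gr
    return (
        float(np.mean(gx * gx)),
        float(np.mean(gx * gy)),
        float(np.mean(gy * gy)),
    )


class TestTiling:
    def test_1440_grid_yields_nine_tiles(self):
        img = np.ones((1440, 1440))
        assert len(tile_rois(img, roi_px=480)) == 9

    def test_single_tile_image(self):
        assert len(tile_rois(np.ones((480, 480)), roi_px=480)) == 1

    def test_origins_match_index_arithmetic(self):
        img = np.ones((200, 300))
        tiles = tile_rois(img, roi_px=64)
        got = [origin for _, origin in tiles]
        expected = [(r, c) for r in range(0, 137, 64) for c in range(0, 237, 64)]
        assert got == expected

    def test_low_content_tiles_dropped(self):
        img = np.full((128, 128), np.nan)
        img[:64, :64] = 1.0  # only the first tile has content
        tiles = tile_rois(img, roi_px=64, min_content_frac=0.1)
        assert [o for _, o in tiles] == [(0, 0)]

    def test_undersized_image_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            tile_rois(np.ones((32, 32)), roi_px=64)


class TestStructureTensor:
    def test_vertical_stripes_have_column_only_gradient(self):
        # intensity varies along columns only → gradient along x, fibers along y
        img = np.tile(np.sin(np.arange(64) * 0.5), (64, 1))
        jxx, jxy, jyy = structure_tensor(img)
        assert jyy <= 1e-6 * jxx
        assert abs(jxy) <= 1e-6 * jxx

    def test_constant_roi_gives_zero_tensor(self):
        jxx, jxy, jyy = structure_tensor(np.full((32, 32), 0.7))
        assert jxx == jxy == jyy == 0.0
        with pytest.raises(UndefinedOrientationError):
            dominant_orientation((jxx, jxy, jyy))

    def test_tensor_is_positive_semidefinite(self):
        rng = np.random.default_rng(0)
        jxx, jxy, jyy = structure_tensor(rng.random((48, 48)))
        assert jxx >= 0 and jyy >= 0
        assert jxy**2 <= jxx * jyy + 1e-12

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        roi = rng.random((32, 32))
        fast = structure_tensor(roi, grad_sigma=1.0)
        slow = naive_structure_tensor(roi, grad_sigma=1.0)
        np.testing.assert_allclose(fast, slow, rtol=1e-8, atol=1e-12)


class TestDominantOrientation:
    @pytest.mark.parametrize("angle", [0, 30, 75, 120, 179])
    def test_grating_angle_recovered_within_one_degree(self, angle):
        theta = dominant_orientation(structure_tensor(grating(angle)))
        assert abs(angular_difference(theta, angle)) <= 1.0

    def test_wraparound_at_period_boundary(self):
        t0 = dominant_orientation(structure_tensor(grating(0)))
        t179 = dominant_orientation(structure_tensor(grating(179)))
        assert abs(angular_difference(t0, t179) - 1.0) <= 1.0

    def test_rotation_equivariance(self):
        base = grating(20, shape=(128, 128))
        rotated = rotate(base, 40, mode="reflect")  # CCW in display coords
        t0 = dominant_orientation(structure_tensor(base[32:96, 32:96]))
        t1 = dominant_orientation(structure_tensor(rotated[32:96, 32:96]))
        assert abs(angular_difference(t1, t0 + 40)) <= 2.0

    def test_invariant_to_intensity_scale_and_offset(self):
        img = grating(55)
        t0 = dominant_orientation(structure_tensor(img))
        t1 = dominant_orientation(structure_tensor(3.7 * img + 10.0))
        assert abs(angular_difference(t0, t1)) <= 1e-9


class TestCoherency:
    def test_perfect_grating_is_fully_coherent(self):
        assert coherency(structure_tensor(grating(30))) >= 0.99

    def test_isotropic_noise_is_incoherent(self):
        rng = np.random.default_rng(2)
        assert coherency(structure_tensor(rng.normal(size=(256, 256)))) <= 0.1

    def test_crossed_gratings_cancel(self):
        crossed = grating(0, (128, 128)) + grating(90, (128, 128))
        assert coherency(structure_tensor(crossed)) <= 0.05

    def test_invariant_to_rotation_and_scaling(self):
        spec = PhantomSpec(shape=(128, 128), seed=3, angle_jitter_deg=15)
        img, _, _ = render_fibers(spec)
        c0 = coherency(structure_tensor(img.data))
        c_scaled = coherency(structure_tensor(5.0 * img.data))
        assert c_scaled == pytest.approx(c0, abs=1e-12)
        c_rot = coherency(structure_tensor(rotate(img.data, 30, mode="constant")))
        assert c_rot == pytest.approx(c0, abs=0.1)

    def test_zero_trace_reported_missing(self):
        assert np.isnan(coherency((0.0, 0.0, 0.0)))


class TestPhantomRecovery:
    def test_fiber_angle_recovered_and_coherency_decreases_with_jitter(self):
        coherencies = []
        for jitter in (0.0, 20.0, 60.0):
            spec = PhantomSpec(
                shape=(192, 192), seed=4, angle_mean_deg=35.0,
                angle_jitter_deg=jitter, n_fibers=80,
            )
            img, _, _ = render_fibers(spec)
            tensor = structure_tensor(img.data)
            if jitter == 0.0:
                theta = dominant_orientation(tensor)
                assert abs(angular_difference(theta, 35.0)) <= 3.0
            coherencies.append(coherency(tensor))
        assert coherencies[0] > coherencies[1] > coherencies[2]

    def test_roi_metrics_table_schema(self):
        img = grating(40, shape=(128, 128))
        df = roi_metrics(img, roi_px=64)
        assert list(df.columns) == [
            "roi_row", "roi_col", "orientation_deg", "coherency", "valid_frac"
        ]
        assert len(df) == 4
        assert ((df["orientation_deg"] >= 0) & (df["orientation_deg"] < 180)).all()
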