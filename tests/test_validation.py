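"""Boundary F-score, angular agreement, Bland–Altman, and correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfmirsi.io_core import PixelMask
from rfmirsi.labels import density_filter
from rfmirsi.collagen_map import threshold_map
from rfmirsi.validation import (
    angular_difference,
    bf_curve,
    bf_score,
    bland_altman,
    circular_pearson,
    extract_boundary,
    pearson_r,
)


def brute_force_bf(pred, gt, tol):
    """All-pairs boundary distance re-computation of the BF-score."""
    pb = np.argwhere(extract_boundary(PixelMask(pred)).data)
    gb = np.argwhere(extract_boundary(PixelMask(gt)).data)
    if len(pb) == 0 and len(gb) == 0:
        return 1.0
    if len(pb) == 0 or len(gb) == 0:
        return 0.0
    d = np.sqrt(((pb[:, None, :] - gb[None, :, :]) ** 2).sum(-1))
    precision = float((d.min(axis=1) <= tol + 1e-9).mean())
    recall = float((d.min(axis=0) <= tol + 1e-9).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


class TestExtractBoundary:
    def test_solid_block_has_perimeter_ring(self):
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True  # 5×5 block → 16-pixel ring
        b = extract_boundary(PixelMask(mask))
        assert b.count() == 16
        assert not b.data[3:6, 3:6].any()

    def test_single_pixel_is_its_own_boundary(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        assert np.array_equal(extract_boundary(PixelMask(mask)).data, mask)

    def test_image_edge_counts_as_outside(self):
        b = extract_boundary(PixelMask(np.ones((4, 4), dtype=bool)))
        assert b.data[0].all() and not b.data[1, 1]

    def test_matches_per_pixel_neighbor_scan(self):
        rng = np.random.default_rng(0)
        mask = rng.random((32, 32)) > 0.5
        got = extract_boundary(PixelMask(mask)).data
        h, w = mask.shape
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    assert not got[r, c]
                    continue
                has_false = False
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                            has_false = True
                assert got[r, c] == has_false


class TestBfScore:
    def test_identical_masks_score_one(self):
        rng = np.random.default_rng(1)
        m = PixelMask(rng.random((20, 20)) > 0.5)
        for tol in (0, 3, 8):
            assert bf_score(m, m, tol) == 1.0

    def test_single_pixels_five_apart(self):
        a = np.zeros((12, 12), dtype=bool)
        b = np.zeros((12, 12), dtype=bool)
        a[3, 3] = True
        b[3, 8] = True
        assert bf_score(PixelMask(a), PixelMask(b), 4) == 0.0
        assert bf_score(PixelMask(a), PixelMask(b), 5) == 1.0

    def test_empty_mask_conventions(self):
        empty = PixelMask(np.zeros((8, 8), dtype=bool))
        full = PixelMask(np.ones((8, 8), dtype=bool))
        assert bf_score(empty, empty, 2) == 1.0
        assert bf_score(empty, full, 2) == 0.0
        assert bf_score(full, empty, 2) == 0.0

    def test_matches_all_pairs_oracle_at_all_tolerances(self):
        rng = np.random.default_rng(2)
        pred = rng.random((64, 64)) > 0.55
        gt = rng.random((64, 64)) > 0.55
        for tol in range(9):
            fast = bf_score(PixelMask(pred), PixelMask(gt), tol)
            assert fast == pytest.approx(brute_force_bf(pred, gt, tol), abs=1e-12)

    def test_symmetric_in_pred_and_gt(self):
        rng = np.random.default_rng(3)
        a = PixelMask(rng.random((40, 40)) > 0.6)
        b = PixelMask(rng.random((40, 40)) > 0.6)
        for tol in (0, 2, 5):
            assert bf_score(a, b, tol) == pytest.approx(bf_score(b, a, tol))

    def test_zero_tolerance_is_exact_boundary_overlap(self):
        rng = np.random.default_rng(4)
        a = PixelMask(rng.random((32, 32)) > 0.5)
        b = PixelMask(rng.random((32, 32)) > 0.5)
        pb, gb = extract_boundary(a).data, extract_boundary(b).data
        tp_p = (pb & gb).sum() / pb.sum()
        tp_g = (pb & gb).sum() / gb.sum()
        expected = 0.0 if tp_p + tp_g == 0 else 2 * tp_p * tp_g / (tp_p + tp_g)
        assert bf_score(a, b, 0) == pytest.approx(expected)


class TestBfCurve:
    def test_nondecreasing_in_tolerance(self, holdout_bundle, default_model):
        from rfmirsi.collagen_map import predict_map
        from rfmirsi.preprocess import preprocess_cube

        model, _ = default_model
        processed, tissue, _ = preprocess_cube(holdout_bundle.cube)
        pm = predict_map(processed, tissue, model)
        gt = density_filter(holdout_bundle.collagen_mask_true)
        tab = bf_curve(pm, gt, p_thresholds=[0.5], tolerances=list(range(1, 9)),
                       roi_px=64)
        means = tab.sort_values("tolerance_px")["bf_mean"].to_numpy()
        assert np.all(np.diff(means) >= 0)

    def test_cells_equal_scalar_bf_composition(self):
        rng = np.random.default_rng(5)
        prob = rng.random((64, 64))
        gt = PixelMask(rng.random((64, 64)) > 0.5)
        tab = bf_curve(prob, gt, p_thresholds=[0.4, 0.6], tolerances=[1, 3],
                       roi_px=32)
        for row in tab.itertuples():
            final = density_filter(threshold_map(prob, row.p), 6).data
            scores = [
                bf_score(
                    PixelMask(final[r : r + 32, c : c + 32]),
                    PixelMask(gt.data[r : r + 32, c : c + 32]),
                    row.tolerance_px,
                )
                for r in (0, 32)
                for c in (0, 32)
            ]
            assert row.bf_mean == pytest.approx(np.mean(scores))
            assert row.n_rois == 4


class TestAngularDifference:
    def test_wraps_across_period(self):
        assert angular_difference(10, 170) == pytest.approx(20)
        assert angular_difference(170, 10) == pytest.approx(-20)

    def test_zero_for_equal_angles(self):
        assert angular_difference(42.5, 42.5) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 179), st.integers(0, 179))
    def test_range_and_congruence(self, a, b):
        d = angular_difference(a, b)
        assert -90 < d <= 90
        assert (d - (a - b)) % 180 == pytest.approx(0, abs=1e-9)


class TestBlandAltman:
    def test_identical_series_zero_mean_and_sd(self):
        x = np.array([10.0, 50.0, 120.0])
        mean, sd, table = bland_altman(x, x)
        assert mean == 0.0 and sd == 0.0
        assert list(table.columns) == ["mean_deg", "diff_deg"]

    def test_constant_offset(self):
        x = np.array([20.0, 60.0, 100.0])
        mean, sd, _ = bland_altman(x + 10.0, x)
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_wrapped_normal_spread(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(0, 180, 300)
        x = (base + rng.normal(0, 15, 300)) % 180
        _, sd, _ = bland_altman(x, base)
        assert 12 <= sd <= 18

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 10)
        y = rng.uniform(0, 10, 10)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y) == pytest.approx(num / den)

    def test_constant_input_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(pearson_r(np.ones(5), np.arange(5.0)))


class TestPlantedAgreement:
    def test_shared_true_angles_with_jitter_correlate(self):
        # 50 ROIs spanning [0,180), independent 5° jitter per modality
        rng = np.random.default_rng(8)
        true = rng.uniform(0, 180, 50)
        a = (true + rng.normal(0, 5, 50)) % 180
        b = (true + rng.normal(0, 5, 50)) % 180
        assert circular_pearson(a, b) >= 0.9
        # raw-degree Pearson after resolving the 0/180 identification
        b_unwrapped = a - angular_difference(a, b)
        assert pearson_r(a, b_unwrapped) >= 0.9
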