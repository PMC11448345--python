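"""Agreement metrics between predicted collagen maps and SHG ground truth.

Segmentation agreement uses the boundary F-score (BF-score): precision is
the fraction of predicted-boundary pixels lying within a Euclidean pixel
tolerance of any ground-truth boundary pixel, recall the converse, and the
score their harmonic mean. The tolerance (swept 0–8 px) absorbs the
residual multimodal registration error that a plain pixel F-score would
punish.

Morphometric agreement uses Pearson correlation of per-ROI dominant
orientation and coherency, plus Bland–Altman statistics of the wrapped
(180°-periodic) orientation differences, signed as predicted − SHG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from rfmirsi.io_core import PixelMask
from rfmirsi.labels import density_filter
from rfmirsi.collagen_map import threshold_map

__all__ = [
    "ValidationReport",
    "extract_boundary",
    "bf_score",
    "bf_curve",
    "angular_difference",
    "bland_altman",
    "pearson_r",
    "circular_pearson",
]


@dataclass
class ValidationReport:
    """Summary of one validation run.

    ``bf_by_tolerance`` maps pixel tolerance → (mean, sd) of the per-ROI
    BF-score at the default probability threshold. The wrapped-correlation
    alternative for orientations is reported alongside the raw-degree
    Pearson because correlation of circular data is convention-sensitive.
    """

    bf_by_tolerance: dict[int, tuple[float, float]]
    pearson_orientation: float
    pearson_orientation_circular: float
    pearson_coherency: float
    bland_altman_mean_deg: float
    bland_altman_sd_deg: float
    n_rois: int
    bf_table: pd.DataFrame | None = field(default=None, repr=False)
    roi_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "bf_by_tolerance": {
                str(t): {"mean": m, "sd": s}
                for t, (m, s) in self.bf_by_tolerance.items()
            },
            "pearson_orientation": self.pearson_orientation,
            "pearson_orientation_circular": self.pearson_orientation_circular,
            "pearson_coherency": self.pearson_coherency,
            "bland_altman_mean_deg": self.bland_altman_mean_deg,
            "bland_altman_sd_deg": self.bland_altman_sd_deg,
            "n_rois": self.n_rois,
        }


def extract_boundary(mask: PixelMask) -> PixelMask:
    """True mask pixels with an 8-connected false (or out-of-image) neighbor."""
    padded = np.pad(mask.data, 1, mode="constant", constant_values=False)
    eroded = ndimage.binary_erosion(
        padded, structure=np.ones((3, 3), dtype=bool), border_value=False
    )[1:-1, 1:-1]
    return PixelMask(mask.data & ~eroded)


def bf_score(pred: PixelMask, gt: PixelMask, tolerance_px: float) -> float:
    """Boundary F-score of a predicted mask against ground truth.

    Both masks empty → 1 (vacuous agreement); exactly one empty → 0.
    Distance queries use a Euclidean distance transform of each boundary,
    equivalent to the all-pairs definition.
    """
    if pred.shape != gt.shape:
        raise ValueError("masks must share a shape")
    if tolerance_px < 0:
        raise ValueError("tolerance must be ≥ 0")
    pb = extract_boundary(pred).data
    gb = extract_boundary(gt).data
    if not pb.any() and not gb.any():
        return 1.0
    if not pb.any() or not gb.any():
        return 0.0
    dist_to_gt = ndimage.distance_transform_edt(~gb)
    dist_to_pred = ndimage.distance_transform_edt(~pb)
    # small epsilon guards float error in the EDT at exact integer radii
    tol = tolerance_px + 1e-9
    precision = float(np.mean(dist_to_gt[pb] <= tol))
    recall = float(np.mean(dist_to_pred[gb] <= tol))
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def bf_curve(
    pred_prob: np.ndarray,
    gt: PixelMask,
    p_thresholds: list[float] = (0.5,),
    tolerances: list[int] = tuple(range(1, 9)),
    min_neighbors: int = 6,
    roi_px: int | None = None,
) -> pd.DataFrame:
    """Mean ± sd per-ROI BF-score over probability and pixel tolerances.

    For each probability threshold the map is binarized (strict >) and
    density-filtered, then scored per ROI against the ground-truth mask at
    every tolerance. ``roi_px=None`` treats the whole image as one ROI.
    Returns a DataFrame with columns p, tolerance_px, bf_mean, bf_sd, n_rois.
    """
    pred_prob = np.asarray(pred_prob, dtype=float)
    if pred_prob.shape != gt.shape:
        raise ValueError("probability map and ground truth shapes differ")

    def _tiles(arr):
        if roi_px is None:
            return [(arr, (0, 0))]
        h, w = arr.shape
        return [
            (arr[r : r + roi_px, c : c + roi_px], (r, c))
            for r in range(0, h - roi_px + 1, roi_px)
            for c in range(0, w - roi_px + 1, roi_px)
        ]

    gt_tiles = _tiles(gt.data)
    if not gt_tiles:
        raise ValueError("no ROIs to score")
    records = []
    for p in p_thresholds:
        final = density_filter(threshold_map(pred_prob, p), min_neighbors).data
        pred_tiles = _tiles(final)
        for tol in tolerances:
            scores = [
                bf_score(PixelMask(pt), PixelMask(gtt), tol)
                for (pt, _), (gtt, _) in zip(pred_tiles, gt_tiles)
            ]
            records.append(
                {
                    "p": p,
                    "tolerance_px": tol,
                    "bf_mean": float(np.mean(scores)),
                    "bf_sd": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                    "n_rois": len(scores),
                }
            )
    return pd.DataFrame.from_records(records)


def angular_difference(a_deg, b_deg):
    """Signed difference a − b of 180°-periodic orientations, in (−90, 90]."""
    a = np.asarray(a_deg, dtype=float)
    b = np.asarray(b_deg, dtype=float)
    d = 90.0 - np.mod(90.0 - (a - b), 180.0)
    if d.ndim == 0:
        return float(d)
    return d


def bland_altman(x, y) -> tuple[float, float, pd.DataFrame]:
    """Agreement of paired orientation measurements (x − y, wrapped).

    Returns (mean difference, sample sd of differences, per-pair table with
    columns mean_deg and diff_deg for plotting).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diffs = angular_difference(x, y)
    table = pd.DataFrame({"mean_deg": (x + y) / 2.0, "diff_deg": diffs})
    return float(np.mean(diffs)), float(np.std(diffs, ddof=1)), table


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; NaN (with a warning) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need ≥3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Pearson correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def circular_pearson(a_deg, b_deg) -> float:
    """Fisher–Lee circular correlation of 180°-periodic orientations.

    Angles are doubled to map the axial data onto the circle before
    applying the circular correlation coefficient.
    """
    a = np.deg2rad(2.0 * np.asarray(a_deg, dtype=float))
    b = np.deg2rad(2.0 * np.asarray(b_deg, dtype=float))
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need ≥3 paired values")
    a0 = a - np.arctan2(np.sin(a).sum(), np.cos(a).sum())
    b0 = b - np.arctan2(np.sin(b).sum(), np.cos(b).sum())
    denom = np.sqrt((np.sin(a0) ** 2).sum() * (np.sin(b0) ** 2).sum())
    if denom == 0:
        warnings.warn("degenerate angular spread: circular correlation undefined",
                      stacklevel=2)
        return float("nan")
    return float((np.sin(a0) * np.sin(b0)).sum() / denom)
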