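"""End-to-end training and validation workflows.

Training: register SHG → binarize + density-filter labels → tissue mask →
band exclusion → unit normalization → PCA denoising → balanced training
set → forest fit. Validation: the same preprocessing on held-out data (PCA
refit on the validation set, never shared with training), probability map,
threshold + density filter, per-ROI BF-score sweep, structure-tensor
morphometrics of both modalities, Pearson and Bland–Altman agreement.

Training/validation disjointness is machine-enforced: the model records
the tissue ids it was trained on and :func:`run_validation` refuses inputs
that reuse any of them. All randomness flows from one top-level seed via
named substreams (labels subsampling, forest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

from rfmirsi.classifier import CollagenForest, train
from rfmirsi.collagen_map import predict_map
from rfmirsi.exceptions import ProvenanceError
from rfmirsi.io_core import GrayImage, LandmarkSet, PixelMask, SpectralCube
from rfmirsi.labels import assemble_training_set, binarize_shg, density_filter
from rfmirsi.morphometrics import roi_metrics
from rfmirsi.preprocess import PreprocessConfig, preprocess_cube
from rfmirsi.registration import fit_affine, registration_residual, warp_image
from rfmirsi.validation import (
    ValidationReport,
    bf_curve,
    bland_altman,
    circular_pearson,
    pearson_r,
)

__all__ = ["TrainingConfig", "ValidationConfig", "run_training", "run_validation"]


def _substream(seed: int, name: str) -> int:
    """Named, order-independent substream seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _config_hash(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class TrainingConfig:
    cube: SpectralCube
    shg: GrayImage
    landmarks: LandmarkSet
    tissue_id: str = "train-0"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    shg_frac_of_max: float = 0.05
    min_neighbors: int = 6
    # binarize after warping intensity (default) or warp a pre-binarized mask
    binarize_after_warp: bool = True
    n_trees: int = 50
    mtry: int | None = None
    seed: int = 0


@dataclass
class ValidationConfig:
    cube: SpectralCube
    shg: GrayImage
    landmarks: LandmarkSet
    tissue_id: str = "val-0"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    shg_frac_of_max: float = 0.05
    min_neighbors: int = 6
    p_threshold: float = 0.5
    p_thresholds: tuple = (0.5, 0.55, 0.6, 0.65, 0.7)
    tolerances: tuple = tuple(range(1, 9))
    roi_px: int = 64
    grad_sigma: float = 1.0


def _registered_collagen_labels(
    cube: SpectralCube,
    shg: GrayImage,
    landmarks: LandmarkSet,
    frac_of_max: float,
    min_neighbors: int,
    binarize_after_warp: bool,
) -> tuple[PixelMask, GrayImage, float]:
    """Warp SHG onto the MIRSI grid and derive the collagen label mask."""
    t = fit_affine(landmarks)
    residual = registration_residual(t, landmarks)
    out_shape = cube.shape[:2]
    shg_reg = warp_image(shg, t, out_shape, interp="bilinear")
    if binarize_after_warp:
        mask = binarize_shg(shg_reg, frac_of_max)
    else:
        from rfmirsi.registration import warp_mask

        mask = warp_mask(binarize_shg(shg, frac_of_max), t, out_shape)
    return density_filter(mask, min_neighbors), shg_reg, residual


def run_training(config: TrainingConfig) -> tuple[CollagenForest, dict]:
    """Train the forest from one co-registered MIRSI/SHG acquisition.

    Returns the fitted model and a JSON-serializable run log (class counts,
    OOB error, seeds, config hash).
    """
    collagen, _, residual = _registered_collagen_labels(
        config.cube,
        config.shg,
        config.landmarks,
        config.shg_frac_of_max,
        config.min_neighbors,
        config.binarize_after_warp,
    )
    processed, tissue, variance_fraction = preprocess_cube(
        config.cube, config.preprocess
    )
    ts = assemble_training_set(
        processed,
        tissue,
        collagen,
        balance=True,
        seed=_substream(config.seed, "labels-subsample"),
        tissue_id=config.tissue_id,
    )
    model = train(
        ts,
        n_trees=config.n_trees,
        mtry=config.mtry,
        seed=_substream(config.seed, "forest"),
    )
    n_pos, n_neg = ts.class_counts
    log = {
        "stage": "training",
        "tissue_id": config.tissue_id,
        "n_collagen": n_pos,
        "n_non_collagen": n_neg,
        "oob_error": model.oob_error_,
        "pca_variance_fraction": variance_fraction,
        "registration_residual_px": residual,
        "n_features": model.n_features_,
        "mtry": model.mtry_,
        "seed": config.seed,
        "config_hash": _config_hash(
            {
                "tissue_id": config.tissue_id,
                "frac_of_max": config.shg_frac_of_max,
                "min_neighbors": config.min_neighbors,
                "n_trees": config.n_trees,
                "mtry": config.mtry,
                "seed": config.seed,
                "preprocess": vars(config.preprocess),
            }
        ),
    }
    return model, log


def run_validation(config: ValidationConfig, model: CollagenForest) -> ValidationReport:
    """Validate a trained model on held-out data.

    Refuses to run if the validation tissue id was used in training.
    """
    trained_on = getattr(model, "training_tissue_ids_", set())
    if config.tissue_id in trained_on:
        raise ProvenanceError(
            f"tissue {config.tissue_id!r} was used for training; validation "
            "requires disjoint data"
        )
    collagen_gt, shg_reg, _ = _registered_collagen_labels(
        config.cube,
        config.shg,
        config.landmarks,
        config.shg_frac_of_max,
        config.min_neighbors,
        binarize_after_warp=True,
    )
    processed, tissue, _ = preprocess_cube(config.cube, config.preprocess)
    prob = predict_map(processed, tissue, model)

    bf_table = bf_curve(
        prob,
        collagen_gt,
        p_thresholds=list(config.p_thresholds),
        tolerances=list(config.tolerances),
        min_neighbors=config.min_neighbors,
        roi_px=config.roi_px,
    )
    at_default = bf_table[bf_table["p"] == config.p_threshold]
    bf_by_tolerance = {
        int(row.tolerance_px): (float(row.bf_mean), float(row.bf_sd))
        for row in at_default.itertuples()
    }

    # orientation/coherency on the continuous probability map vs the
    # registered SHG intensity image
    pred_m = roi_metrics(prob, roi_px=config.roi_px, grad_sigma=config.grad_sigma)
    shg_m = roi_metrics(
        shg_reg.data, roi_px=config.roi_px, grad_sigma=config.grad_sigma
    )
    merged = pred_m.merge(shg_m, on=["roi_row", "roi_col"], suffixes=("_pred", "_shg"))
    ok = (
        merged[
            [
                "orientation_deg_pred",
                "orientation_deg_shg",
                "coherency_pred",
                "coherency_shg",
            ]
        ]
        .notna()
        .all(axis=1)
    )
    merged = merged[ok]
    a = merged["orientation_deg_pred"].to_numpy()
    b = merged["orientation_deg_shg"].to_numpy()
    mean_d, sd_d, _ = bland_altman(a, b)
    report = ValidationReport(
        bf_by_tolerance=bf_by_tolerance,
        pearson_orientation=pearson_r(a, b),
        pearson_orientation_circular=circular_pearson(a, b),
        pearson_coherency=pearson_r(
            merged["coherency_pred"].to_numpy(), merged["coherency_shg"].to_numpy()
        ),
        bland_altman_mean_deg=mean_d,
        bland_altman_sd_deg=sd_d,
        n_rois=int(len(merged)),
        bf_table=bf_table,
        roi_table=merged,
    )
    return report
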