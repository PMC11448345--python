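"""Landmark-based 2D affine registration of SHG onto the MIRSI grid.

The MIRSI hyperspectral raster is the fixed frame; the SHG image is the
moving frame. A least-squares affine (scaling, rotation, shear,
translation) is fit to manually picked point pairs and the moving image is
resampled onto the fixed grid by inverse mapping. Non-affine distortions
(barrel distortion, coverslip deformation) are not modeled; residual
misalignment is absorbed downstream by the boundary F-score's pixel
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from rfmirsi.exceptions import DegenerateGeometryError
from rfmirsi.io_core import GrayImage, LandmarkSet, PixelMask

__all__ = [
    "AffineTransform2D",
    "fit_affine",
    "warp_image",
    "warp_mask",
    "registration_residual",
]

_ORDER = {"nearest": 0, "bilinear": 1}


@dataclass
class AffineTransform2D:
    """A 2×3 matrix mapping moving ``(row, col)`` to fixed ``(row, col)``."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2×3, got {self.matrix.shape}")
        if abs(np.linalg.det(self.matrix[:, :2])) <= 1e-12:
            raise DegenerateGeometryError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """Similarity transform: rotate (about the origin), scale, translate.

        Rotation is counterclockwise in (row, col) display coordinates.
        """
        th = np.deg2rad(rotation_deg)
        lin = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return cls(np.column_stack([lin, np.asarray(translation, dtype=float)]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map N×2 (row, col) points from the moving to the fixed frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform2D":
        lin_inv = np.linalg.inv(self.matrix[:, :2])
        return AffineTransform2D(
            np.column_stack([lin_inv, -lin_inv @ self.matrix[:, 2]])
        )

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return self ∘ other (apply ``other`` first)."""
        lin = self.matrix[:, :2] @ other.matrix[:, :2]
        t = self.matrix[:, :2] @ other.matrix[:, 2] + self.matrix[:, 2]
        return AffineTransform2D(np.column_stack([lin, t]))


def fit_affine(landmarks: LandmarkSet) -> AffineTransform2D:
    """Least-squares affine minimizing Σ‖T(moving_i) − fixed_i‖².

    With exactly three non-collinear pairs the fit interpolates exactly.
    """
    m = landmarks.moving_points
    f = landmarks.fixed_points
    design = np.column_stack([m, np.ones(len(m))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(m).max())) < 3:
        raise DegenerateGeometryError("landmark points are collinear")
    coef, *_ = np.linalg.lstsq(design, f, rcond=None)
    # coef is 3×2 mapping [row, col, 1] → [row, col]; transpose to 2×3.
    return AffineTransform2D(coef.T)


def warp_image(
    image: GrayImage,
    t: AffineTransform2D,
    out_shape: tuple[int, int],
    interp: str = "bilinear",
) -> GrayImage:
    """Resample the moving image onto the fixed grid by inverse mapping.

    Output pixel ``q`` takes the value of the moving image at ``T⁻¹(q)``;
    samples falling outside the moving image are 0.
    """
    if interp not in _ORDER:
        raise ValueError(f"interp must be one of {sorted(_ORDER)}")
    inv = t.inverse()
    warped = ndimage.affine_transform(
        image.data,
        inv.matrix[:, :2],
        offset=inv.matrix[:, 2],
        output_shape=tuple(out_shape),
        order=_ORDER[interp],
        mode="constant",
        cval=0.0,
    )
    # Bilinear interpolation of non-negative data can produce tiny negative
    # ringing at float precision; clamp.
    return GrayImage(np.maximum(warped, 0.0), image.pixel_size_um)


def warp_mask(
    mask: PixelMask, t: AffineTransform2D, out_shape: tuple[int, int]
) -> PixelMask:
    """Warp a binary mask with nearest-neighbor interpolation ({0,1}-preserving)."""
    warped = warp_image(
        GrayImage(mask.data.astype(float)), t, out_shape, interp="nearest"
    )
    return PixelMask(warped.data > 0.5)


def registration_residual(t: AffineTransform2D, landmarks: LandmarkSet) -> float:
    """RMS distance ‖T(moving_i) − fixed_i‖ in fixed-frame pixels.

    A quality gate for manual landmarks: one grossly wrong pair inflates the
    residual well above the noise floor of careful picking.
    """
    pred = t.apply(landmarks.moving_points)
    return float(
        np.sqrt(np.mean(np.sum((pred - landmarks.fixed_points) ** 2, axis=1)))
    )
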