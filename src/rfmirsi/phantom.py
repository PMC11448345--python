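"""Synthetic MIRSI/SHG phantoms with known ground truth.

Every test fixture in the package is produced here from a seed: a
two-class spectral cube (collagen vs non-collagen tissue on a bare
substrate), a fibrous SHG rendering with known per-ROI orientation, a known
affine offset between the two modalities, and landmark pairs consistent
with that offset.

Spectra are sums of parametric Gaussian bands on the 950–1800 cm⁻¹ axis at
2 cm⁻¹ spacing (426 bands). Both classes share the protein backbone bands
(amide I ≈ 1655 cm⁻¹, amide II ≈ 1550 cm⁻¹, amide III ≈ 1240 cm⁻¹); the
collagen class additionally carries a proline/hydroxyproline-region excess
centered in 1360–1420 cm⁻¹ — the planted informative block that importance
analyses should recover. Band placement is qualitative: amplitudes and
widths are package choices, not digitized instrument curves. Detector
noise is i.i.d. Gaussian per band; the amide contrast is constructed so
the amide-difference tissue rule recovers the true tissue footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line_aa

from rfmirsi.io_core import GrayImage, LandmarkSet, PixelMask, SpectralCube
from rfmirsi.registration import AffineTransform2D

__all__ = ["PhantomSpec", "PhantomBundle", "render_fibers", "render_cube", "make_bundle"]

#: (center cm⁻¹, width cm⁻¹, amplitude a.u.) Gaussian bands shared by both
#: tissue classes: amide I, amide II, amide III.
BASE_PROFILE = ((1655.0, 25.0, 0.75), (1550.0, 22.0, 0.45), (1240.0, 30.0, 0.25))

#: Center and width of the collagen-specific proline-region excess band.
PROLINE_CENTER, PROLINE_WIDTH = 1390.0, 22.0


@dataclass
class PhantomSpec:
    """Generation parameters; defaults define the study conditions.

    ``noise_sd`` (a.u. per band) is set so the default classification task
    sits near 5% out-of-bag error (0.075 a.u. per band): hard enough to exercise probability
    thresholds, easy enough for deterministic behavior.
    """

    shape: tuple[int, int] = (128, 128)
    wn_start: float = 950.0
    wn_stop: float = 1800.0
    wn_step: float = 2.0
    collagen_profile: tuple = BASE_PROFILE
    non_collagen_profile: tuple = BASE_PROFILE
    proline_delta: float = 0.06
    baseline: float = 0.15
    noise_sd: float = 0.075
    n_fibers: int = 60
    angle_mean_deg: float = 40.0
    angle_jitter_deg: float = 10.0
    fiber_width_px: int = 3
    shg_floor: float = 0.2
    # dark counts off by default so shg_true is positive exactly on fibers
    shg_background_sd: float = 0.0
    roi_px: int = 64
    tissue_margin_px: int = 8
    affine: AffineTransform2D = field(
        default_factory=lambda: AffineTransform2D.from_params(
            rotation_deg=2.0, scale=1.0, translation=(3.0, -2.0)
        )
    )
    seed: int = 0

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.arange(self.wn_start, self.wn_stop + 0.5 * self.wn_step, self.wn_step)

    def __post_init__(self) -> None:
        if self.angle_jitter_deg < 0:
            raise ValueError("angle_jitter_deg must be ≥ 0")
        if any(amp < 0 for _, _, amp in self.collagen_profile):
            raise ValueError("profiles must be non-negative")


@dataclass
class PhantomBundle:
    """One simulated acquisition with its complete ground truth."""

    cube: SpectralCube
    shg_true: GrayImage
    shg_observed: GrayImage
    collagen_mask_true: PixelMask
    tissue_mask_true: PixelMask
    orientation_true: dict[tuple[int, int], float]
    landmarks: LandmarkSet
    spec: PhantomSpec
    clip_fraction: float = 0.0


def _profile(axis: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(axis)
    for center, width, amp in bands:
        out += amp * np.exp(-((axis - center) ** 2) / (2.0 * width**2))
    return out


def _circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Mean of 180°-periodic angles via angle doubling."""
    doubled = np.deg2rad(2.0 * angles_deg)
    mean = np.arctan2(np.sin(doubled).mean(), np.cos(doubled).mean())
    return float(np.degrees(mean) / 2.0 % 180.0)


def render_fibers(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[GrayImage, PixelMask, dict[tuple[int, int], float]]:
    """Draw anti-aliased fiber segments; return image, support mask, ROI truth.

    Fiber angles are drawn from a normal distribution around
    ``angle_mean_deg`` (wrapped to [0, 180)); the per-ROI true orientation
    is the circular mean of the angles of fibers whose centers fall in that
    ROI (NaN where no fiber center lands).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    h, w = spec.shape
    img = np.zeros((h, w), dtype=float)
    centers, angles = [], []
    if spec.n_fibers == 0:
        import warnings

        warnings.warn("zero fibers requested: empty phantom", stacklevel=2)
    half_len = 0.35 * min(h, w)
    for _ in range(spec.n_fibers):
        angle = rng.normal(spec.angle_mean_deg, spec.angle_jitter_deg) % 180.0
        cr = rng.uniform(0, h - 1)
        cc = rng.uniform(0, w - 1)
        # fiber direction: counterclockwise from +x (col) axis with y upward,
        # i.e. drow = -sin, dcol = +cos
        d = np.array([-np.sin(np.deg2rad(angle)), np.cos(np.deg2rad(angle))])
        p0 = np.array([cr, cc]) - half_len * d
        p1 = np.array([cr, cc]) + half_len * d
        rr, cc_, val = line_aa(
            int(round(p0[0])), int(round(p0[1])), int(round(p1[0])), int(round(p1[1]))
        )
        keep = (rr >= 0) & (rr < h) & (cc_ >= 0) & (cc_ < w)
        np.maximum.at(img, (rr[keep], cc_[keep]), val[keep])
        centers.append((cr, cc))
        angles.append(angle)
    if spec.fiber_width_px > 1:
        img = ndimage.grey_dilation(img, size=(spec.fiber_width_px,) * 2)
    mask = PixelMask(img > 0)
    # Lift fiber intensities above the binarization threshold (anti-aliased
    # edges would otherwise dip below ~5% of max) and add PMT dark counts
    # below it outside fibers.
    img = np.where(mask.data, spec.shg_floor + (1.0 - spec.shg_floor) * img, 0.0)
    if spec.shg_background_sd > 0:
        dark = np.abs(rng.normal(0.0, spec.shg_background_sd, size=img.shape))
        img = np.where(mask.data, img, dark)

    orientation_true: dict[tuple[int, int], float] = {}
    centers_arr = np.array(centers) if centers else np.empty((0, 2))
    angles_arr = np.array(angles)
    for r0 in range(0, h - spec.roi_px + 1, spec.roi_px):
        for c0 in range(0, w - spec.roi_px + 1, spec.roi_px):
            if len(centers_arr):
                inside = (
                    (centers_arr[:, 0] >= r0)
                    & (centers_arr[:, 0] < r0 + spec.roi_px)
                    & (centers_arr[:, 1] >= c0)
                    & (centers_arr[:, 1] < c0 + spec.roi_px)
                )
            else:
                inside = np.zeros(0, dtype=bool)
            orientation_true[(r0, c0)] = (
                _circular_mean_deg(angles_arr[inside]) if inside.any() else float("nan")
            )
    return GrayImage(img), mask, orientation_true


def render_cube(
    spec: PhantomSpec,
    collagen_mask: PixelMask,
    tissue_mask: PixelMask,
    rng: np.random.Generator | None = None,
) -> tuple[SpectralCube, float]:
    """Render the hyperspectral cube for given class masks.

    Tissue pixels get their class profile plus i.i.d. Gaussian band noise;
    bare-substrate pixels get noise only. Negative values after noise are
    clipped at zero; the clipped fraction is returned alongside the cube.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    axis = spec.wavenumbers
    h, w = spec.shape
    # broad baseline absorbance keeps tissue noise clear of the zero clip
    base = spec.baseline + _profile(axis, spec.non_collagen_profile)
    coll = spec.baseline + _profile(axis, spec.collagen_profile) + spec.proline_delta * np.exp(
        -((axis - PROLINE_CENTER) ** 2) / (2.0 * PROLINE_WIDTH**2)
    )
    data = rng.normal(0.0, spec.noise_sd, size=(h, w, len(axis)))
    data[tissue_mask.data] += base
    data[collagen_mask.data & tissue_mask.data] += coll - base
    clipped = data < 0
    clip_fraction = float(clipped.mean())
    np.clip(data, 0.0, None, out=data)
    return SpectralCube(data, axis, pixel_size_um=1.35), clip_fraction


def make_bundle(spec: PhantomSpec) -> PhantomBundle:
    """Compose fibers, cube, affine-perturbed SHG, and consistent landmarks.

    The observed SHG is the true rendering resampled through the spec's
    affine (``observed(p) = true(T(p))``), so warping the observed image
    with the fitted transform recovers the true, registered SHG. Landmarks
    are exact corresponding points under that affine.
    """
    rng = np.random.default_rng(spec.seed)
    shg_true, fiber_mask, orientation_true = render_fibers(spec, rng)

    h, w = spec.shape
    m = spec.tissue_margin_px
    tissue = np.zeros((h, w), dtype=bool)
    tissue[m : h - m, m : w - m] = True
    tissue_mask = PixelMask(tissue)
    collagen_mask = PixelMask(fiber_mask.data & tissue)

    cube, clip_fraction = render_cube(spec, collagen_mask, tissue_mask, rng)

    t = spec.affine
    if np.allclose(t.matrix, AffineTransform2D.identity().matrix):
        observed = shg_true.data.copy()
    else:
        observed = ndimage.affine_transform(
            shg_true.data,
            t.matrix[:, :2],
            offset=t.matrix[:, 2],
            order=1,
            mode="constant",
            cval=0.0,
        )
    shg_observed = GrayImage(np.maximum(observed, 0.0), shg_true.pixel_size_um)

    # landmark pairs exact under T: fixed on the MIRSI grid, moving = T⁻¹(fixed)
    fixed_pts = np.array(
        [
            [m + 2.0, m + 2.0],
            [m + 2.0, w - m - 3.0],
            [h - m - 3.0, m + 2.0],
            [h - m - 3.0, w - m - 3.0],
            [h / 2.0, w / 2.0],
        ]
    )
    moving_pts = t.inverse().apply(fixed_pts)
    landmarks = LandmarkSet(moving_pts, fixed_pts)

    return PhantomBundle(
        cube=cube,
        shg_true=shg_true,
        shg_observed=shg_observed,
        collagen_mask_true=collagen_mask,
        tissue_mask_true=tissue_mask,
        orientation_true=orientation_true,
        landmarks=landmarks,
        spec=spec,
        clip_fraction=clip_fraction,
    )
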