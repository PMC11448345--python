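"""Spectral preprocessing: tissue masking, band exclusion, normalization, PCA denoising.

The fixed pipeline order is mask → exclude → normalize → denoise:

1. A pixel is tissue if its amide I contrast — absorbance at 1655 cm⁻¹ minus
   absorbance at the non-absorbing 1760 cm⁻¹ reference — lies in
   [0.1, 2.0] a.u. (inclusive). Proteins are present in any tissue, so amide
   I contrast separates tissue from bare substrate. The rule is evaluated on
   raw absorbance, before normalization.
2. The 1440–1480 cm⁻¹ region (inclusive) is removed: QCL-based instruments
   switch lasers there and the band is unreliable.
3. Each tissue spectrum is scaled to unit Euclidean norm, removing
   thickness/density variation.
4. The spectra are denoised by projecting onto the top principal components
   (default 40) and reconstructing in band space. The PCA basis is fit per
   dataset — training and validation each get their own basis, never shared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from rfmirsi.io_core import PixelMask, SpectralCube

__all__ = [
    "PreprocessConfig",
    "compute_tissue_mask",
    "exclude_bands",
    "unit_normalize",
    "pca_denoise",
    "preprocess_cube",
]


@dataclass
class PreprocessConfig:
    """Preprocessing parameters.

    Attributes
    ----------
    amide_band : float
        Amide I band position, cm⁻¹.
    ref_band : float
        Non-absorbing reference band, cm⁻¹.
    diff_low, diff_high : float
        Inclusive bounds on the amide-contrast tissue rule, a.u.
    exclude_low, exclude_high : float
        Inclusive bounds of the unreliable laser-switching region, cm⁻¹.
    n_components : int
        Principal components kept for denoising.
    """

    amide_band: float = 1655.0
    ref_band: float = 1760.0
    diff_low: float = 0.1
    diff_high: float = 2.0
    exclude_low: float = 1440.0
    exclude_high: float = 1480.0
    n_components: int = 40

    def __post_init__(self) -> None:
        if not self.diff_low < self.diff_high:
            raise ValueError("diff_low must be < diff_high")
        if not self.exclude_low < self.exclude_high:
            raise ValueError("exclude_low must be < exclude_high")
        if self.n_components < 1:
            raise ValueError("n_components must be ≥ 1")


def compute_tissue_mask(
    cube: SpectralCube, cfg: PreprocessConfig | None = None
) -> PixelMask:
    """Tissue mask from amide I contrast on raw absorbance.

    True exactly where ``diff_low ≤ A(amide) − A(ref) ≤ diff_high``
    (inclusive bounds).
    """
    cfg = cfg or PreprocessConfig()
    i_amide = cube.band_index(cfg.amide_band)
    i_ref = cube.band_index(cfg.ref_band)
    diff = cube.data[:, :, i_amide] - cube.data[:, :, i_ref]
    return PixelMask((diff >= cfg.diff_low) & (diff <= cfg.diff_high))


def exclude_bands(cube: SpectralCube, cfg: PreprocessConfig | None = None) -> SpectralCube:
    """Remove all bands with ``exclude_low ≤ ν ≤ exclude_high`` (inclusive).

    Inclusive endpoints make a 426-band 950–1800 cm⁻¹ axis at 2 cm⁻¹ spacing
    lose exactly the 21 bands in 1440–1480, leaving 405 features.
    """
    cfg = cfg or PreprocessConfig()
    keep = (cube.wavenumbers < cfg.exclude_low) | (cube.wavenumbers > cfg.exclude_high)
    if not keep.any():
        raise ValueError("band exclusion would remove the entire axis")
    if keep.all():
        return cube
    return SpectralCube(
        cube.data[:, :, keep], cube.wavenumbers[keep], cube.pixel_size_um
    )


def unit_normalize(spectra: np.ndarray) -> np.ndarray:
    """Scale each row to unit Euclidean norm.

    Raises if a row has zero norm — that signals a non-tissue pixel that
    leaked through the mask.
    """
    spectra = np.asarray(spectra, dtype=float)
    norms = np.linalg.norm(spectra, axis=-1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"zero-norm spectrum at row {int(zero[0])}")
    return spectra / norms[..., None]


def pca_denoise(
    spectra: np.ndarray, n_components: int = 40
) -> tuple[np.ndarray, float]:
    """Reconstruct spectra from their top principal components.

    Returns
    -------
    denoised : ndarray, same shape as input
        Mean + projection of the centered data onto the top ``n_components``
        principal axes, mapped back to band space.
    variance_fraction : float
        Explained-variance share of the kept components, in [0, 1].
    """
    spectra = np.asarray(spectra, dtype=float)
    n, b = spectra.shape
    if n_components >= min(n, b):
        warnings.warn(
            f"n_components={n_components} ≥ min(N, B)={min(n, b)}; "
            "returning identity reconstruction",
            stacklevel=2,
        )
        return spectra.copy(), 1.0
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(spectra)
    denoised = pca.inverse_transform(scores)
    return denoised, float(pca.explained_variance_ratio_.sum())


def preprocess_cube(
    cube: SpectralCube, cfg: PreprocessConfig | None = None
) -> tuple[SpectralCube, PixelMask, float]:
    """Full pipeline: mask → exclude → normalize → denoise.

    Only tissue pixels are normalized/denoised; non-tissue pixels are zeroed
    in the returned cube and must be ignored downstream via the mask.

    Returns ``(preprocessed cube, tissue mask, PCA variance fraction)``.
    """
    cfg = cfg or PreprocessConfig()
    tissue = compute_tissue_mask(cube, cfg)
    reduced = exclude_bands(cube, cfg)
    out = np.zeros_like(reduced.data)
    variance_fraction = 1.0
    if tissue.count() > 0:
        rows = unit_normalize(reduced.data[tissue.data])
        rows, variance_fraction = pca_denoise(rows, cfg.n_components)
        out[tissue.data] = rows
    processed = SpectralCube(out, reduced.wavenumbers, reduced.pixel_size_um)
    return processed, tissue, variance_fraction
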