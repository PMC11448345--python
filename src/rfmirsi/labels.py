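"""SHG binarization, density filtering, and training-set assembly.

Registered SHG intensity images are binarized at a fraction of their
maximum (default ~5%, set so dark counts outside tissue are removed while
true collagen signal is kept). A density filter then removes isolated
"non-structural" collagen pixels: a true pixel survives only if at least
six of its eight neighbors are true. The surviving mask, intersected with
the tissue mask, labels each MIRSI spectrum collagen/non-collagen; the
majority class is subsampled so the training set is balanced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from rfmirsi.io_core import GrayImage, PixelMask, SpectralCube

__all__ = ["TrainingSet", "binarize_shg", "density_filter", "assemble_training_set"]

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=int)


@dataclass
class TrainingSet:
    """Labeled spectra with per-row provenance.

    Attributes
    ----------
    X : ndarray, shape (N, F)
        Preprocessed spectra (band-excluded, unit-normalized, denoised).
    y : ndarray of bool, shape (N,)
        True where the pixel is collagen.
    provenance : DataFrame with columns tissue_id, row, col
        Origin of each spectrum, used to enforce training/validation
        disjointness.
    wavenumbers : ndarray, shape (F,)
        Feature axis in cm⁻¹.
    """

    X: np.ndarray
    y: np.ndarray
    provenance: pd.DataFrame
    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=bool)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X and y shapes disagree")
        if len(self.provenance) != len(self.y):
            raise ValueError("provenance length disagrees with X")
        if self.X.shape[1] != len(self.wavenumbers):
            raise ValueError("feature count disagrees with wavenumber axis")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_collagen, n_non_collagen)."""
        n_pos = int(self.y.sum())
        return n_pos, len(self.y) - n_pos


def binarize_shg(image: GrayImage, frac_of_max: float = 0.05) -> PixelMask:
    """Threshold at ``frac_of_max × max(intensity)`` (≥, so invariant to scaling)."""
    peak = float(image.data.max())
    if peak <= 0:
        raise ValueError("cannot binarize an all-zero image")
    return PixelMask(image.data >= frac_of_max * peak)


def density_filter(mask: PixelMask, min_neighbors: int = 6) -> PixelMask:
    """Keep true pixels with at least ``min_neighbors`` true 8-neighbors.

    Single-pass semantics: neighbor counts come from the input mask, never
    from partially filtered output, so the result is order-independent.
    Pixels outside the image count as false neighbors. The output is a
    subset of the input (anti-extensive).
    """
    if min_neighbors > 8:
        raise ValueError("an 8-connected neighborhood has at most 8 neighbors")
    counts = ndimage.convolve(
        mask.data.astype(int), _NEIGHBOR_KERNEL, mode="constant", cval=0
    )
    return PixelMask(mask.data & (counts >= min_neighbors))


def assemble_training_set(
    cube: SpectralCube,
    tissue: PixelMask,
    collagen: PixelMask,
    balance: bool = True,
    seed: int = 0,
    tissue_id: str = "t0",
) -> TrainingSet:
    """Build a labeled spectral training set from a preprocessed cube.

    Rows are drawn only from tissue pixels; the collagen class is the
    intersection of the collagen and tissue masks (the classifier only ever
    sees tissue spectra, so SHG-positive pixels outside tissue are dropped).
    With ``balance`` the majority class is uniformly subsampled (seeded) to
    the minority count.
    """
    if tissue.shape != cube.shape[:2] or collagen.shape != cube.shape[:2]:
        raise ValueError("masks must share the cube's spatial shape")
    pos = collagen.data & tissue.data
    neg = tissue.data & ~pos
    if not pos.any() or not neg.any():
        raise ValueError("both collagen and non-collagen classes must be non-empty")

    pos_idx = np.argwhere(pos)
    neg_idx = np.argwhere(neg)
    if balance:
        rng = np.random.default_rng(seed)
        n = min(len(pos_idx), len(neg_idx))
        if len(pos_idx) > n:
            pos_idx = pos_idx[rng.choice(len(pos_idx), size=n, replace=False)]
        if len(neg_idx) > n:
            neg_idx = neg_idx[rng.choice(len(neg_idx), size=n, replace=False)]

    coords = np.vstack([pos_idx, neg_idx])
    y = np.zeros(len(coords), dtype=bool)
    y[: len(pos_idx)] = True
    X = cube.data[coords[:, 0], coords[:, 1], :]
    provenance = pd.DataFrame(
        {"tissue_id": tissue_id, "row": coords[:, 0], "col": coords[:, 1]}
    )
    return TrainingSet(X, y, provenance, cube.wavenumbers)
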