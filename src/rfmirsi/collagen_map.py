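"""From per-pixel collagen probabilities to the final binary collagen map.

Probability maps carry NaN outside tissue; that sentinel is excluded from
every downstream statistic. The map is binarized at a probability strictly
above the threshold (default 50% — deliberately permissive so collagen-
containing pixels are caught), then the same density filter used for SHG
labels removes isolated non-structural pixels.
"""

from __future__ import annotations

import numpy as np

from rfmirsi.classifier import CollagenForest
from rfmirsi.io_core import PixelMask, SpectralCube
from rfmirsi.labels import density_filter

__all__ = ["predict_map", "threshold_map", "finalize_map"]


def predict_map(
    cube: SpectralCube, tissue: PixelMask, model: CollagenForest
) -> np.ndarray:
    """Per-pixel collagen probability on tissue; NaN elsewhere.

    The cube must be preprocessed identically to the training data and its
    band axis must equal the model's feature axis.
    """
    if tissue.shape != cube.shape[:2]:
        raise ValueError("tissue mask shape does not match the cube")
    if not np.array_equal(cube.wavenumbers, model.feature_wavenumbers_):
        raise ValueError("cube band axis does not match the model feature axis")
    out = np.full(cube.shape[:2], np.nan)
    if tissue.count() > 0:
        out[tissue.data] = model.predict_proba(cube.data[tissue.data])
    return out


def threshold_map(pm: np.ndarray, p: float = 0.5) -> PixelMask:
    """Binarize a probability map at strict ``probability > p``; NaN → False."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    with np.errstate(invalid="ignore"):
        return PixelMask(np.asarray(pm, dtype=float) > p)


def finalize_map(mask: PixelMask, min_neighbors: int = 6) -> PixelMask:
    """Remove non-structural collagen: same density filter used on labels."""
    return density_filter(mask, min_neighbors=min_neighbors)
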