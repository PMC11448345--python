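"""Hyperspectral cube, image, mask, and landmark I/O.

Coordinate convention, enforced here and inherited by every downstream
module: 0-based ``(row, col)`` indices with the origin at the center of the
top-left pixel. The spectral axis is stored ascending in cm⁻¹; files with a
descending axis are flipped (data and axis together) on read.

Supported cube dialects:

``envi``
    Plain-text ``.hdr`` header plus raw band-sequential (BSQ) float32
    binary, the de-facto exchange format for hyperspectral imagery.
``tiff_stack``
    Multi-page grayscale TIFF (one page per band) with a sidecar text file
    (``<stem>.wavenumbers.txt``, one wavenumber per line).
``npz``
    NumPy archive; bit-exact round trips, used for fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile

from rfmirsi.exceptions import AxisError, FormatError

__all__ = [
    "SpectralCube",
    "GrayImage",
    "PixelMask",
    "LandmarkSet",
    "read_cube",
    "write_cube",
    "read_landmarks",
    "write_landmarks",
    "read_gray_image",
    "write_gray_image",
    "read_mask",
    "write_mask",
]


@dataclass
class SpectralCube:
    """An H×W×B absorbance volume with its wavenumber axis.

    Parameters
    ----------
    data : ndarray, shape (H, W, B)
        Absorbance in arbitrary units; finite, non-negative.
    wavenumbers : ndarray, shape (B,)
        Strictly increasing band axis in cm⁻¹.
    pixel_size_um : float
        Edge length of one pixel in µm.
    """

    data: np.ndarray
    wavenumbers: np.ndarray
    pixel_size_um: float = 1.35

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be H×W×B, got shape {self.data.shape}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("cube has an empty spatial dimension")
        if self.wavenumbers.ndim != 1 or len(self.wavenumbers) != self.data.shape[2]:
            raise ValueError(
                f"band axis length {self.wavenumbers.shape} does not match "
                f"cube band count {self.data.shape[2]}"
            )
        if len(self.wavenumbers) >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        bad = ~np.isfinite(self.data)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(f"cube contains non-finite value at index {idx}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavenumber: float) -> int:
        """Nearest band index, tolerance one band spacing.

        The methods name wavenumbers, not indices; acquisition grids differ,
        so lookups snap to the nearest axis entry but refuse requests farther
        than one band spacing from the axis.
        """
        wn = self.wavenumbers
        i = int(np.argmin(np.abs(wn - wavenumber)))
        spacing = float(np.min(np.diff(wn))) if len(wn) > 1 else np.inf
        if abs(wn[i] - wavenumber) > spacing:
            raise AxisError(
                f"{wavenumber} cm⁻¹ is farther than one band spacing "
                f"({spacing} cm⁻¹) from the axis (nearest: {wn[i]})"
            )
        return i

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralCube):
            return NotImplemented
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.wavenumbers, other.wavenumbers)
            and self.pixel_size_um == other.pixel_size_um
        )


@dataclass
class GrayImage:
    """A single-channel intensity image (e.g. SHG) with pixel size in µm."""

    data: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("image contains non-finite values")
        if (self.data < 0).any():
            raise ValueError("image intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class PixelMask:
    """A boolean H×W raster annotating another raster of the same shape."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __and__(self, other: "PixelMask") -> "PixelMask":
        return PixelMask(self.data & other.data)

    def __invert__(self) -> "PixelMask":
        return PixelMask(~self.data)

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class LandmarkSet:
    """Index-aligned manual point pairs: moving image → fixed image.

    Both point arrays are N×2 ``(row, col)`` in each image's own pixel grid,
    pre-registration.
    """

    moving_points: np.ndarray
    fixed_points: np.ndarray

    def __post_init__(self) -> None:
        self.moving_points = np.asarray(self.moving_points, dtype=float)
        self.fixed_points = np.asarray(self.fixed_points, dtype=float)
        for name, pts in (("moving", self.moving_points), ("fixed", self.fixed_points)):
            if pts.ndim != 2 or pts.shape[1] != 2:
                raise ValueError(f"{name}_points must be N×2, got {pts.shape}")
        if self.moving_points.shape[0] != self.fixed_points.shape[0]:
            raise ValueError("moving and fixed point counts differ")
        if self.moving_points.shape[0] < 3:
            raise ValueError("affine needs ≥3 non-collinear pairs")

    def __len__(self) -> int:
        return self.moving_points.shape[0]


# ---------------------------------------------------------------------------
# ENVI dialect

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _parse_envi_header(path: str) -> dict:
    """Parse the key = value (or key = {list}) lines of an ENVI header."""
    with open(path) as fh:
        text = fh.read()
    fields: dict[str, str] = {}
    key, buf, in_list = None, [], False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_list:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_list = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and "}" not in val:
            buf = [val]
            in_list = True
        else:
            fields[key] = val
    return fields


def _read_envi(path: str) -> SpectralCube:
    hdr_path = path if path.endswith(".hdr") else path + ".hdr"
    bin_path = hdr_path[:-4]
    if not os.path.exists(hdr_path):
        raise FormatError(f"missing ENVI header: {hdr_path}")
    fields = _parse_envi_header(hdr_path)
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields.get("data type", "4"))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"ENVI header missing/invalid dimension fields: {exc}") from exc
    if "wavelength" not in fields:
        raise FormatError("ENVI header has no wavelength list")
    wn_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    try:
        wavenumbers = np.array(
            [float(tok) for tok in wn_text.replace(",", " ").split()], dtype=float
        )
    except ValueError as exc:
        raise FormatError(f"unparsable wavelength list: {exc}") from exc
    if len(wavenumbers) != bands:
        raise FormatError(
            f"header lists {bands} bands but wavelength list has {len(wavenumbers)}"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {dtype_code}")
    dtype = _ENVI_DTYPES[dtype_code]
    interleave = fields.get("interleave", "bsq").lower()
    raw = np.fromfile(bin_path, dtype=dtype)
    expected = lines * samples * bands
    if raw.size != expected:
        raise FormatError(
            f"binary holds {raw.size} values, header implies {expected} "
            f"({lines}×{samples}×{bands})"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unsupported interleave {interleave!r}")
    pixel_size = float(fields.get("pixel size", "1.0").strip("{} "))
    return _finalize_axis(data, wavenumbers, pixel_size)


def _write_envi(cube: SpectralCube, path: str) -> str:
    bin_path = path[:-4] if path.endswith(".hdr") else path
    hdr_path = bin_path + ".hdr"
    data32 = cube.data.astype(np.float32)
    data32.transpose(2, 0, 1).tofile(bin_path)  # BSQ
    wn = " , ".join(f"{w:.6f}" for w in cube.wavenumbers)
    header = (
        "ENVI\n"
        f"samples = {cube.data.shape[1]}\n"
        f"lines = {cube.data.shape[0]}\n"
        f"bands = {cube.data.shape[2]}\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"pixel size = {cube.pixel_size_um}\n"
        f"wavelength = {{ {wn} }}\n"
    )
    with open(hdr_path, "w") as fh:
        fh.write(header)
    return bin_path


# ---------------------------------------------------------------------------
# TIFF-stack and npz dialects


def _sidecar_path(path: str) -> str:
    stem, _ = os.path.splitext(path)
    return stem + ".wavenumbers.txt"


def _read_tiff_stack(path: str) -> SpectralCube:
    sidecar = _sidecar_path(path)
    if not os.path.exists(sidecar):
        raise FormatError(f"missing wavenumber sidecar: {sidecar}")
    try:
        wavenumbers = np.loadtxt(sidecar, dtype=float, ndmin=1)
    except ValueError as exc:
        raise FormatError(f"unparsable wavenumber sidecar: {exc}") from exc
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != len(wavenumbers):
        raise FormatError(
            f"TIFF has {pages.shape[0]} pages but sidecar lists "
            f"{len(wavenumbers)} wavenumbers"
        )
    data = np.moveaxis(pages, 0, 2).astype(float)
    return _finalize_axis(data, wavenumbers, 1.0)


def _write_tiff_stack(cube: SpectralCube, path: str) -> str:
    tifffile.imwrite(path, np.moveaxis(cube.data, 2, 0).astype(np.float32))
    np.savetxt(_sidecar_path(path), cube.wavenumbers, fmt="%.6f")
    return path


def _read_npz(path: str) -> SpectralCube:
    with np.load(path) as archive:
        try:
            data = archive["data"]
            wavenumbers = archive["wavenumbers"]
            pixel_size = float(archive["pixel_size_um"])
        except KeyError as exc:
            raise FormatError(f"npz archive missing array {exc}") from exc
    return _finalize_axis(data, wavenumbers, pixel_size)


def _write_npz(cube: SpectralCube, path: str) -> str:
    np.savez_compressed(
        path,
        data=cube.data,
        wavenumbers=cube.wavenumbers,
        pixel_size_um=cube.pixel_size_um,
    )
    return path


def _finalize_axis(
    data: np.ndarray, wavenumbers: np.ndarray, pixel_size_um: float
) -> SpectralCube:
    # Descending axes are legal on disk; flip data and axis to the in-memory
    # ascending convention.
    if len(wavenumbers) >= 2 and np.all(np.diff(wavenumbers) < 0):
        wavenumbers = wavenumbers[::-1].copy()
        data = data[:, :, ::-1].copy()
    return SpectralCube(data, wavenumbers, pixel_size_um)


_READERS = {"envi": _read_envi, "tiff_stack": _read_tiff_stack, "npz": _read_npz}
_WRITERS = {"envi": _write_envi, "tiff_stack": _write_tiff_stack, "npz": _write_npz}


def read_cube(path: str, dialect: str = "envi") -> SpectralCube:
    """Read a hyperspectral cube; see module docstring for dialects."""
    if dialect not in _READERS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_READERS)}")
    return _READERS[dialect](str(path))


def write_cube(cube: SpectralCube, path: str, dialect: str = "envi") -> str:
    """Write a cube; ``npz`` round-trips bit-exactly, ``envi`` within float32."""
    if dialect not in _WRITERS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_WRITERS)}")
    return _WRITERS[dialect](cube, str(path))


# ---------------------------------------------------------------------------
# Grayscale images and masks


def read_gray_image(path: str, pixel_size_um: float = 1.0) -> GrayImage:
    data = tifffile.imread(str(path)).astype(float)
    return GrayImage(data, pixel_size_um)


def write_gray_image(image: GrayImage, path: str) -> str:
    tifffile.imwrite(str(path), image.data.astype(np.float32))
    return str(path)


def read_mask(path: str) -> PixelMask:
    return PixelMask(tifffile.imread(str(path)) > 0)


def write_mask(mask: PixelMask, path: str) -> str:
    tifffile.imwrite(str(path), mask.data.astype(np.uint8) * 255)
    return str(path)


# ---------------------------------------------------------------------------
# Landmarks


def read_landmarks(path: str) -> LandmarkSet:
    """Read a whitespace/comma-delimited table of point pairs.

    Each non-comment row holds four numbers:
    ``moving_row moving_col fixed_row fixed_col``.
    """
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 numbers, got {len(tokens)}"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell in {line!r}"
                ) from None
    if len(rows) < 3:
        raise ValueError("affine needs ≥3 non-collinear pairs")
    arr = np.array(rows, dtype=float)
    return LandmarkSet(arr[:, :2], arr[:, 2:])


def write_landmarks(landmarks: LandmarkSet, path: str) -> str:
    table = np.hstack([landmarks.moving_points, landmarks.fixed_points])
    np.savetxt(
        str(path),
        table,
        fmt="%.6f",
        header="moving_row moving_col fixed_row fixed_col",
    )
    return str(path)
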