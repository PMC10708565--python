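"""Hyperspectral cube I/O, reflectance calibration and ROI spectra.

Supports a minimal ENVI dialect (text ``.hdr`` plus raw binary cube in
BIL/BIP/BSQ interleave) and a plain-text ``flat_table`` dialect where each
line is one pixel. Reflectance is computed as
``(raw - dark) / (white - dark) * 100`` and is deliberately not clamped:
downstream scatter correction is affine-invariant, so out-of-range values
carry information rather than noise.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import SpectraSet
from .errors import (
    CalibrationError,
    DimensionError,
    FormatError,
    ParameterError,
    ROIError,
)

logger = logging.getLogger(__name__)

_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_ENVI_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HSICube:
    """Raw-intensity hyperspectral cube (rows x cols x bands)."""

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise DimensionError(f"cube must be 3-D, got shape {self.data.shape}")
        rows, cols, bands = self.data.shape
        if rows < 1 or cols < 1:
            raise DimensionError("cube must have at least one pixel")
        if bands != self.wavelengths.size:
            raise DimensionError(
                f"{bands} bands but {self.wavelengths.size} wavelengths"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ParameterError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class CalibrationFrames:
    """White and dark reference frames, 2-D (per pixel) or 3-D (per pixel per band)."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.ndim not in (2, 3) or self.dark.ndim not in (2, 3):
            raise DimensionError("reference frames must be 2-D or 3-D")

    def broadcast_to(self, shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        """White/dark expanded to the cube shape; 3-D frames take precedence as given."""
        out = []
        for frame in (self.white, self.dark):
            arr = frame[:, :, None] if frame.ndim == 2 else frame
            try:
                out.append(np.broadcast_to(arr, shape))
            except ValueError as exc:
                raise DimensionError(
                    f"reference frame shape {frame.shape} not broadcastable to cube {shape}"
                ) from exc
        return out[0], out[1]


@dataclass
class ReflectanceCube:
    """Calibrated reflectance cube (percent) with a validity mask."""

    data: np.ndarray
    wavelengths: np.ndarray
    invalid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.invalid_mask = np.asarray(self.invalid_mask, dtype=bool)
        if self.invalid_mask.shape != self.data.shape:
            raise DimensionError("invalid_mask shape must match data shape")


@dataclass
class ROIMask:
    """Boolean spatial mask after edge erosion."""

    mask: np.ndarray
    margin_px: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise DimensionError("ROI mask must be 2-D")
        if self.margin_px < 0:
            raise ParameterError("margin_px must be non-negative")
        if not self.mask.any():
            raise ROIError("ROI mask has no true pixels")


# ---------------------------------------------------------------------------
# Cube I/O


def _parse_envi_header(path: str) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError(f"{path}: missing ENVI magic line")
    header: dict = {}
    # join brace-delimited multi-line values before splitting into fields
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            items = value.strip("{} \t").split(",")
            header[key] = [item.strip() for item in items if item.strip()]
        else:
            header[key] = value
    return header


def _read_envi(path: str) -> HSICube:
    hdr_path = path if path.endswith(".hdr") else path + ".hdr"
    if not os.path.exists(hdr_path):
        raise FormatError(f"ENVI header not found: {hdr_path}")
    header = _parse_envi_header(hdr_path)
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in header:
            raise FormatError(f"{hdr_path}: missing header field '{key}'")
    cols = int(header["samples"])
    rows = int(header["lines"])
    bands = int(header["bands"])
    dtype_code = int(header["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"{hdr_path}: unsupported 'data type' {dtype_code}")
    interleave = str(header["interleave"]).lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise FormatError(f"{hdr_path}: unsupported 'interleave' {interleave!r}")
    if "wavelength" not in header:
        raise FormatError(f"{hdr_path}: missing header field 'wavelength'")
    try:
        wavelengths = np.array([float(w) for w in header["wavelength"]])
    except ValueError as exc:
        raise FormatError(f"{hdr_path}: non-numeric wavelength entry") from exc
    if wavelengths.size != bands:
        raise DimensionError(
            f"{hdr_path}: {bands} bands but {wavelengths.size} wavelengths"
        )
    data_path = hdr_path[:-4] if os.path.exists(hdr_path[:-4]) else hdr_path[:-4] + ".img"
    if not os.path.exists(data_path):
        raise FormatError(f"ENVI data file not found for header {hdr_path}")
    raw = np.fromfile(data_path, dtype=_ENVI_DTYPES[dtype_code])
    if raw.size != rows * cols * bands:
        raise DimensionError(
            f"{data_path}: expected {rows * cols * bands} values, found {raw.size}"
        )
    if interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    else:  # bsq
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    meta = {k: v for k, v in header.items()}
    return HSICube(data=np.ascontiguousarray(data), wavelengths=wavelengths, meta=meta)


def _read_flat_table(path: str) -> HSICube:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0].lower() != "row" or df.columns[1].lower() != "col":
        raise FormatError(f"{path}: flat-table must start with 'row,col' columns")
    try:
        wavelengths = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength header") from exc
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    data = np.full((rows, cols, wavelengths.size), np.nan)
    data[df["row"].to_numpy(int), df["col"].to_numpy(int)] = df.iloc[:, 2:].to_numpy(float)
    return HSICube(data=data, wavelengths=wavelengths, meta={"source": path})


def read_cube(path: str, dialect: str = "envi") -> HSICube:
    """Read a hyperspectral cube from ``path``.

    ``dialect="envi"`` expects ``path`` (or ``path + ".hdr"``) to be an ENVI
    text header next to its raw binary cube; ``dialect="flat_table"`` expects
    a CSV with columns ``row,col,<wavelength>...``.
    """
    if dialect == "envi":
        return _read_envi(path)
    if dialect == "flat_table":
        if not os.path.exists(path):
            raise FormatError(f"file not found: {path}")
        return _read_flat_table(path)
    raise ParameterError(f"unknown dialect {dialect!r}")


def write_cube(cube: HSICube, path: str, dialect: str = "envi", interleave: str = "bip") -> None:
    """Write a cube in the given dialect (inverse of :func:`read_cube`)."""
    if dialect == "flat_table":
        rows, cols, _ = cube.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        df = pd.DataFrame(cube.data.reshape(rows * cols, -1), columns=[str(float(w)) for w in cube.wavelengths])
        df.insert(0, "col", cc.ravel())
        df.insert(0, "row", rr.ravel())
        df.to_csv(path, index=False, float_format="%.17g")
        return
    if dialect != "envi":
        raise ParameterError(f"unknown dialect {dialect!r}")
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ParameterError(f"unsupported interleave {interleave!r}")
    data = np.asarray(cube.data)
    if data.dtype not in _ENVI_DTYPE_CODES:
        data = data.astype(np.float64)
    rows, cols, bands = data.shape
    if interleave == "bip":
        flat = data
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    else:
        flat = data.transpose(2, 0, 1)
    stem = path[:-4] if path.endswith(".hdr") else path
    flat.tofile(stem)
    wl = ", ".join(str(float(w)) for w in cube.wavelengths)
    with open(stem + ".hdr", "w", encoding="utf-8") as fh:
        fh.write("ENVI\n")
        fh.write(f"samples = {cols}\nlines = {rows}\nbands = {bands}\n")
        fh.write(f"data type = {_ENVI_DTYPE_CODES[data.dtype]}\n")
        fh.write(f"interleave = {interleave}\nbyte order = 0\n")
        fh.write("wavelength units = Nanometers\n")
        fh.write("wavelength = {" + wl + "}\n")


# ---------------------------------------------------------------------------
# Calibration and ROI extraction


def calibrate_reflectance(cube: HSICube, frames: CalibrationFrames) -> ReflectanceCube:
    """Convert raw counts to percent reflectance against white/dark references.

    ``reflectance = (raw - dark) / (white - dark) * 100``; voxels where
    ``white - dark <= 0`` are flagged invalid and set to NaN.
    """
    white, dark = frames.broadcast_to(cube.shape)
    denom = white - dark
    invalid = denom <= 0
    if invalid.all():
        raise CalibrationError("white - dark is non-positive everywhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        data = (cube.data.astype(float) - dark) / denom * 100.0
    data = np.where(invalid, np.nan, data)
    n_out = np.count_nonzero((data < 0) | (data > 100))
    if n_out:
        logger.info("calibrate_reflectance: %d voxels outside [0, 100]%% kept unclamped", n_out)
    return ReflectanceCube(data=data, wavelengths=cube.wavelengths.copy(), invalid_mask=invalid)


def build_roi_mask(foreground: np.ndarray, margin_mm: float, px_per_mm: float) -> ROIMask:
    """Erode the foreground so pixels within ``margin_mm`` of the edge are excluded.

    Erosion uses the full 3x3 (square / Chebyshev) structuring element, one
    iteration per pixel of margin; ``margin_px = round(margin_mm * px_per_mm)``.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if foreground.ndim != 2:
        raise DimensionError("foreground mask must be 2-D")
    if not foreground.any():
        raise ROIError("foreground mask is empty")
    if margin_mm < 0 or px_per_mm <= 0:
        raise ParameterError("margin_mm must be >= 0 and px_per_mm > 0")
    margin_px = int(round(margin_mm * px_per_mm))
    if margin_px == 0:
        return ROIMask(mask=foreground.copy(), margin_px=0)
    structure = np.ones((3, 3), dtype=bool)
    mask = ndimage.binary_erosion(
        foreground, structure=structure, iterations=margin_px, border_value=0
    )
    if not mask.any():
        raise ROIError(
            f"margin of {margin_px} px erases the whole ROI; use a smaller margin_mm"
        )
    return ROIMask(mask=mask, margin_px=margin_px)


def roi_mean_spectrum(cube: ReflectanceCube, roi: ROIMask) -> np.ndarray:
    """Per-band arithmetic mean of valid ROI pixels."""
    if roi.mask.shape != cube.data.shape[:2]:
        raise DimensionError(
            f"ROI shape {roi.mask.shape} does not match cube spatial dims {cube.data.shape[:2]}"
        )
    pixels = cube.data[roi.mask]  # (n_roi, bands)
    valid = ~cube.invalid_mask[roi.mask]
    counts = valid.sum(axis=0)
    if np.any(counts == 0):
        raise ROIError("ROI has bands with no valid pixels")
    return np.where(valid, pixels, 0.0).sum(axis=0) / counts


def average_replicates(spectra: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise mean of replicate scan vectors (applied after ROI means)."""
    if len(spectra) == 0:
        raise ParameterError("need at least one replicate spectrum")
    arrays = [np.asarray(s, dtype=float) for s in spectra]
    length = arrays[0].size
    for a in arrays:
        if a.ndim != 1 or a.size != length:
            raise DimensionError("replicate spectra must be 1-D of equal length")
    return np.mean(arrays, axis=0)


# ---------------------------------------------------------------------------
# Tabular spectra I/O


def read_spectra_table(path: str, form: str | None = None) -> SpectraSet:
    """Read a delimited spectra table: first column sample_id, then wavelengths."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a sample_id column plus at least one band")
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample ids")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric wavelength header") from exc
    X = df.iloc[:, 1:].to_numpy(float)
    order = np.argsort(wavelengths, kind="stable")
    if not np.array_equal(order, np.arange(order.size)):
        logger.info("read_spectra_table: wavelength columns re-sorted ascending")
        wavelengths, X = wavelengths[order], X[:, order]
    return SpectraSet(X=X, wavelengths=wavelengths, sample_ids=ids, form=form)


def write_spectra_table(spectra: SpectraSet, path: str) -> None:
    """Write a SpectraSet as a delimited table (inverse of read_spectra_table)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.DataFrame(spectra.X, columns=[str(float(w)) for w in spectra.wavelengths])
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
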