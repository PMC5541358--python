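"""Detector image I/O and the Pattern data model.

A :class:`Pattern` couples a 2D intensity grid (raw detector counts, arbitrary
units) with a boolean validity mask.  Invalid pixels stand in for the "missing
data" (NaN) points of the original workflow: beamstop flare, detector-module
gaps and thresholded outliers.  All downstream reductions are mask-aware.

Pixel coordinates are 0-based ``(row, col)`` with row increasing downward.
Integer images are promoted to float64 without rescaling: raw counts are
preserved.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Stable column order of the results table.
RESULT_COLUMNS = [
    "source",
    "centre_row",
    "centre_col",
    "d_period_nm",
    "fibril_diameter_nm",
    "bragg_spacing_nm",
    "order_param",
    "bragg_spacing_comp_nm",
    "order_param_comp",
    "stages",
]


@dataclass
class Pattern:
    """2D scattering pattern: intensity grid + validity mask + provenance."""

    intensity: np.ndarray
    valid_mask: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.intensity.ndim != 2:
            raise ValidationError("intensity must be a 2D array")
        if self.intensity.shape != self.valid_mask.shape:
            raise ValidationError(
                f"intensity shape {self.intensity.shape} != mask shape "
                f"{self.valid_mask.shape}"
            )
        if not np.isfinite(self.intensity[self.valid_mask]).all():
            raise ValidationError("valid pixels must hold finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def replace(self, **kwargs) -> "Pattern":
        """Return a copy with the given fields replaced (shape immutable)."""
        new = dataclasses.replace(self, **kwargs)
        if new.shape != self.shape:
            raise ValidationError("Pattern shape is immutable")
        return new

    def copy(self) -> "Pattern":
        return Pattern(self.intensity.copy(), self.valid_mask.copy(), self.source)


@dataclass
class ResultsRow:
    """One line of the batch results table; absent values stay ``None``."""

    source: str
    centre_row: Optional[float] = None
    centre_col: Optional[float] = None
    d_period_nm: Optional[float] = None
    fibril_diameter_nm: Optional[float] = None
    bragg_spacing_nm: Optional[float] = None
    order_param: Optional[float] = None
    bragg_spacing_comp_nm: Optional[float] = None
    order_param_comp: Optional[float] = None
    stages: str = ""

    def __post_init__(self):
        for name in ("d_period_nm", "fibril_diameter_nm", "bragg_spacing_nm",
                     "bragg_spacing_comp_nm"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be positive or absent, got {v}")


def load_pattern(path) -> Pattern:
    """Read a TIFF/PNG/JPEG detector image into a :class:`Pattern`.

    All pixels start valid.  Multi-channel images are collapsed to a single
    channel by the unweighted channel mean (scientific detector data is
    expected single-channel; a warning is logged).
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile

            data = tifffile.imread(str(path))
        else:
            import imageio.v3 as iio

            data = iio.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path named
        raise IOError(f"could not read image {path}: {exc}") from exc

    data = np.asarray(data)
    if data.ndim == 3:
        if data.shape[2] > 4:
            raise FormatError(f"unsupported channel layout {data.shape} in {path}")
        logger.warning(
            "%s has %d channels; collapsing to single channel by unweighted mean",
            path.name, data.shape[2],
        )
        data = data.astype(np.float64).mean(axis=2)
    elif data.ndim != 2:
        raise FormatError(f"unsupported image dimensionality {data.shape} in {path}")

    intensity = data.astype(np.float64)
    return Pattern(intensity, np.ones(intensity.shape, dtype=bool), source=path.name)


def save_pattern(pattern: Pattern, path) -> None:
    """Write the intensity grid as a 32-bit float TIFF (lossless for float32)."""
    import tifffile

    tifffile.imwrite(str(path), pattern.intensity.astype(np.float32))


def _row_to_dict(row: ResultsRow) -> dict:
    d = dataclasses.asdict(row)
    return {k: d[k] for k in RESULT_COLUMNS}


def write_results(rows: Sequence[ResultsRow], path) -> None:
    """Write the results table as CSV (header + one line per pattern).

    Column order is fixed by :data:`RESULT_COLUMNS`; absent values serialize
    as empty cells, never zeros; numbers keep 8 significant digits.
    """
    if not rows:
        raise ValidationError("rows must be nonempty")
    frame = pd.DataFrame([_row_to_dict(r) for r in rows], columns=RESULT_COLUMNS)
    try:
        frame.to_csv(path, index=False, float_format="%.8g", na_rep="")
    except OSError as exc:
        raise IOError(f"could not write results to {path}: {exc}") from exc


def read_results(path) -> pd.DataFrame:
    """Read back a results CSV (round-trip companion of :func:`write_results`)."""
    return pd.read_csv(path)


def write_orientation_profile(angles_deg, aligned, path) -> None:
    """Write a two-column CSV ``angle_deg, aligned_intensity``."""
    angles = np.asarray(angles_deg, dtype=float)
    values = np.asarray(aligned, dtype=float)
    if angles.shape != values.shape or angles.ndim != 1:
        raise ValidationError("angles and aligned values must be equal-length vectors")
    if angles.size and np.any(np.diff(angles) <= 0):
        raise ValidationError("angles must be strictly increasing")
    frame = pd.DataFrame({"angle_deg": angles, "aligned_intensity": values})
    try:
        frame.to_csv(path, index=False, float_format="%.8g")
    except OSError as exc:
        raise IOError(f"could not write orientation profile to {path}: {exc}") from exc
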