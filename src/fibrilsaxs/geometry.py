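"""Pattern centring and pixel-to-spacing calibration.

The pattern centre (straight-through beam position) is found by an algebraic
least-squares circle fit (Kåsa form) to points selected on a calibrant
diffraction ring.  Calibration maps pixel radius R to scattering-vector
magnitude K via a single calibrant reflection of known d-spacing:

    K(R) = k_per_pixel * R,    k_per_pixel = (2*pi / d_cal) / r_cal

using the small-angle linear approximation (the analysis works entirely in
pixel positions; sample-to-detector distance and wavelength are never needed).
The K convention is K = 2*pi/d, so d(R) = d_cal * r_cal / R and a reflection
of order n at radius R corresponds to a period n * d_cal * r_cal / R.

Azimuth convention (used everywhere): 0 deg along +col, increasing
counter-clockwise in standard image display (row down), i.e.
phi = atan2(-(row - centre_row), col - centre_col) in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import GeometryError, ValidationError


class Centre(NamedTuple):
    """Sub-pixel beam centre in (row, col) pixel coordinates."""

    row: float
    col: float


@dataclass(frozen=True)
class CircleFit:
    centre: Centre
    radius: float
    rms_residual: float


@dataclass(frozen=True)
class Calibration:
    """Linear pixel-radius -> scattering-vector calibration from one reflection."""

    r_cal: float  # calibrant peak radius, pixels
    d_cal: float  # assigned d-spacing, nm

    def __post_init__(self):
        if not (self.r_cal > 0 and self.d_cal > 0):
            raise ValidationError("r_cal and d_cal must be positive")

    @property
    def k_per_pixel(self) -> float:
        """nm^-1 per pixel."""
        return (2.0 * np.pi / self.d_cal) / self.r_cal

    def K(self, radius_px):
        """Scattering-vector magnitude (nm^-1) at the given pixel radius."""
        return self.k_per_pixel * np.asarray(radius_px, dtype=float)

    def spacing_from_pixel(self, r_peak: float, order: int = 1) -> float:
        """Real-space period (nm) of an order-n reflection at radius r_peak."""
        if not r_peak > 0:
            raise ValidationError(f"r_peak must be positive, got {r_peak}")
        if not (isinstance(order, (int, np.integer)) and order >= 1):
            raise ValidationError(f"order must be a positive integer, got {order}")
        return order * self.d_cal * self.r_cal / r_peak

    def pixel_from_spacing(self, d_nm: float, order: int = 1) -> float:
        """Inverse of :meth:`spacing_from_pixel`."""
        if not d_nm > 0:
            raise ValidationError(f"d_nm must be positive, got {d_nm}")
        return order * self.d_cal * self.r_cal / d_nm


def make_calibration(r_cal: float, d_cal: float) -> Calibration:
    """Build a calibration from the calibrant peak position and its d-spacing."""
    return Calibration(r_cal=float(r_cal), d_cal=float(d_cal))


def spacing_from_pixel(cal: Calibration, r_peak: float, order: int = 1) -> float:
    return cal.spacing_from_pixel(r_peak, order)


def fit_circle(points: Sequence[Sequence[float]]) -> CircleFit:
    """Algebraic least-squares circle through >=3 non-collinear points.

    Kåsa form: minimize sum of (|p - c|^2 - r^2)^2, a linear least-squares
    problem.  Exact (zero residual) for concyclic input.  Points are centred
    on their mean first for numerical conditioning; the result is identical
    in exact arithmetic.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array of (row, col)")
    if pts.shape[0] < 3:
        raise GeometryError(f"need at least 3 points, got {pts.shape[0]}")

    mean = pts.mean(axis=0)
    u = pts[:, 0] - mean[0]
    v = pts[:, 1] - mean[1]
    A = np.column_stack([2.0 * u, 2.0 * v, np.ones(len(u))])
    rhs = u * u + v * v
    sol, _, rank, sv = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3 or sv[-1] < 1e-12 * sv[0]:
        raise GeometryError("points are collinear (or otherwise degenerate)")
    cu, cv, c = sol
    radius = float(np.sqrt(c + cu * cu + cv * cv))
    if not np.isfinite(radius) or radius <= 0:
        raise GeometryError("circle fit produced a non-positive radius")
    centre = Centre(row=float(cu + mean[0]), col=float(cv + mean[1]))
    dists = np.hypot(pts[:, 0] - centre.row, pts[:, 1] - centre.col)
    rms = float(np.sqrt(np.mean((dists - radius) ** 2)))
    return CircleFit(centre=centre, radius=radius, rms_residual=rms)


def radial_coordinate(shape: tuple[int, int], centre: Centre):
    """Per-pixel radius (px) and azimuth (deg, [0, 360)) grids about ``centre``.

    Azimuth 0 deg along +col, increasing counter-clockwise in standard image
    display (one row *above* the centre is 90 deg).
    """
    nrows, ncols = shape
    if not (-0.5 <= centre.row <= nrows - 0.5 and -0.5 <= centre.col <= ncols - 0.5):
        raise ValidationError(f"centre {centre} outside pattern bounds {shape}")
    rows = np.arange(nrows, dtype=float)[:, None] - centre.row
    cols = np.arange(ncols, dtype=float)[None, :] - centre.col
    radius = np.hypot(rows, cols)
    azimuth = np.degrees(np.arctan2(-rows, cols)) % 360.0
    return radius, azimuth
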