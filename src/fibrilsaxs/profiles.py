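"""Mask-aware reduction of the 2D pattern to 1D radial and azimuthal profiles.

Bins report the arithmetic MEAN of their valid pixels, not the sum: with
detector gaps and threshold masks a per-bin sum depends on the arbitrary
number of surviving pixels, whereas the mean is gap-robust.  The per-bin valid
count ``n_valid`` is retained so sums stay recoverable
(sum over bins of intensity * n_valid == sum of the contributing pixels).

Pixels are assigned to bins by centre-of-pixel rounding; there is no
area-weighted pixel splitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyDataError, ValidationError
from .geometry import Centre, radial_coordinate
from .patterns import Pattern


@dataclass
class RadialProfile:
    """Azimuthally integrated profile: 1-px bins, NaN where a bin is empty."""

    radius_px: np.ndarray
    intensity: np.ndarray
    n_valid: np.ndarray

    def value_at(self, r: float) -> float:
        """Intensity of the bin nearest to radius ``r``."""
        idx = int(np.argmin(np.abs(self.radius_px - r)))
        return float(self.intensity[idx])


@dataclass
class AzimuthalProfile:
    """Radially integrated profile over an annulus; uniform circular bins."""

    azimuth_deg: np.ndarray
    intensity: np.ndarray
    n_valid: np.ndarray


def _azimuth_selector(azimuth: np.ndarray, ranges) -> np.ndarray:
    """Boolean selector for azimuths inside any (lo, hi) range (wrapping)."""
    sel = np.zeros(azimuth.shape, dtype=bool)
    for lo, hi in ranges:
        width = (hi - lo) % 360.0
        if width == 0:
            width = 360.0
        sel |= ((azimuth - lo) % 360.0) <= width
    return sel


def integrate_radial(
    p: Pattern,
    centre: Centre,
    r_min: float = 0.0,
    r_max: float | None = None,
    azimuth_ranges: Sequence[tuple[float, float]] | None = None,
    bin_px: float = 1.0,
) -> RadialProfile:
    """Azimuthally integrate into radial bins of ``bin_px`` pixels.

    Bin b collects valid pixels whose rounded radius (in bins) equals b;
    intensity is the mean of those pixels.  ``azimuth_ranges`` optionally
    restricts the integration to azimuthal sectors (fibre-diffraction sector
    integration), e.g. ``[(-25, 25), (155, 205)]`` for an equatorial sector.
    """
    if r_max is None:
        nrows, ncols = p.shape
        r_max = min(centre.row, centre.col, nrows - 1 - centre.row, ncols - 1 - centre.col)
    if not r_min < r_max:
        raise ValidationError(f"require r_min < r_max, got {r_min} >= {r_max}")
    if bin_px <= 0:
        raise ValidationError("bin_px must be positive")

    radius, azimuth = radial_coordinate(p.shape, centre)
    rbin = np.rint(radius / bin_px).astype(int)
    b_lo = int(np.ceil(r_min / bin_px))
    b_hi = int(np.floor(r_max / bin_px))
    sel = p.valid_mask & (rbin >= b_lo) & (rbin <= b_hi)
    if azimuth_ranges is not None:
        sel &= _azimuth_selector(azimuth, azimuth_ranges)
    if not sel.any():
        raise EmptyDataError("no valid pixels in the requested radial range")

    idx = rbin[sel]
    counts = np.bincount(idx, minlength=b_hi + 1)[b_lo : b_hi + 1]
    sums = np.bincount(idx, weights=p.intensity[sel], minlength=b_hi + 1)[b_lo : b_hi + 1]
    with np.errstate(invalid="ignore"):
        intensity = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(
        radius_px=np.arange(b_lo, b_hi + 1, dtype=float) * bin_px,
        intensity=intensity,
        n_valid=counts,
    )


def integrate_azimuthal(
    p: Pattern,
    centre: Centre,
    r_inner: float,
    r_outer: float,
    bin_deg: float = 1.0,
) -> AzimuthalProfile:
    """Radially integrate the annulus [r_inner, r_outer] into azimuth bins.

    Bin centred at phi collects valid annulus pixels with azimuth in
    [phi - bin/2, phi + bin/2); bins wrap circularly over [0, 360).
    """
    if not 0 <= r_inner < r_outer:
        raise ValidationError("require 0 <= r_inner < r_outer")
    nbins = int(round(360.0 / bin_deg))
    if nbins < 1 or abs(nbins * bin_deg - 360.0) > 1e-9:
        raise ValidationError("bin_deg must divide 360")

    radius, azimuth = radial_coordinate(p.shape, centre)
    sel = p.valid_mask & (radius >= r_inner) & (radius <= r_outer)
    if not sel.any():
        raise EmptyDataError("no valid pixels in the requested annulus")

    idx = (np.floor(((azimuth[sel] + bin_deg / 2.0) % 360.0) / bin_deg)).astype(int) % nbins
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=p.intensity[sel], minlength=nbins)
    with np.errstate(invalid="ignore"):
        intensity = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return AzimuthalProfile(
        azimuth_deg=np.arange(nbins, dtype=float) * bin_deg,
        intensity=intensity,
        n_valid=counts,
    )
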