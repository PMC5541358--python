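"""Pre-processing corrections applied to the raw pattern.

Stage order in the pipeline is fixed as: load -> negative-offset correction ->
background image subtraction -> threshold masking -> gap filling.  Thresholds
(LL/UL) mark outlier pixels invalid; the radial limits Ri/Rio do NOT invalidate
pixels — they are integration limits recorded for the reduction stages.

Gap filling exploits the order-2 rotational symmetry of fibre scattering about
the beam centre: each invalid pixel is first populated from its point
reflection through the centre (nearest-pixel rounding), then any remainder is
filled by circular linear interpolation in azimuth along its integer-radius
ring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import Centre, radial_coordinate
from .patterns import Pattern

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaskSpec:
    """Outlier thresholds and radial integration limits (LL/UL, Ri/Rio)."""

    lower_limit: float = -np.inf
    upper_limit: float = np.inf
    r_inner: float = 0.0
    r_outer: float = np.inf

    def __post_init__(self):
        if not self.lower_limit < self.upper_limit:
            raise ValidationError("require LL < UL")
        if not (0 <= self.r_inner < self.r_outer):
            raise ValidationError("require 0 <= Ri < Rio")


def correct_negative(p: Pattern) -> Pattern:
    """Shift the whole matrix so the (valid-pixel) minimum becomes exactly 0.

    Applied only when the minimum is negative (detector calibration offsets);
    otherwise the pattern is returned unchanged.  Pairwise intensity
    differences are preserved.
    """
    if not p.valid_mask.any():
        return p
    vmin = float(p.intensity[p.valid_mask].min())
    if vmin >= 0:
        return p
    return p.replace(intensity=p.intensity - vmin)


def subtract_background_image(p: Pattern, bg: Pattern | None, scale: float = 1.0) -> Pattern:
    """Subtract ``scale * bg`` pixel-wise; masks are ANDed.

    With no background supplied the background matrix is zeros (identity).
    """
    if bg is None:
        return p
    if bg.shape != p.shape:
        raise ValidationError(f"background shape {bg.shape} != pattern shape {p.shape}")
    return p.replace(
        intensity=p.intensity - scale * bg.intensity,
        valid_mask=p.valid_mask & bg.valid_mask,
    )


def apply_mask(p: Pattern, spec: MaskSpec, centre: Centre | None = None) -> Pattern:
    """Invalidate pixels with intensity < LL or > UL (treated as missing data).

    The annulus limits Ri/Rio in ``spec`` are integration limits only and do
    not change any pixel here; surviving pixel values are never altered.
    """
    outlier = p.valid_mask & (
        (p.intensity < spec.lower_limit) | (p.intensity > spec.upper_limit)
    )
    if not outlier.any():
        return p
    return p.replace(valid_mask=p.valid_mask & ~outlier)


def fill_gaps(
    p: Pattern,
    centre: Centre,
    r_min: float = 0.0,
    r_max: float | None = None,
) -> Pattern:
    """Populate invalid pixels from order-2 symmetry, then ring interpolation.

    Pass 1: each invalid pixel takes the value of its point reflection through
    the centre (nearest-pixel rounding of the reflected coordinate) when that
    partner is a valid pixel of the *input*.
    Pass 2: remaining invalid pixels are filled by linear interpolation in
    azimuth between the nearest valid pixels on the same integer-radius ring
    (circular, wrapping 360 deg).  A ring with no valid pixel at all is left
    invalid with a warning.

    ``r_min``/``r_max`` optionally restrict filling to rings whose rounded
    radius lies in that range (e.g. the Ri/Rio integration annulus).
    Idempotent: a second call is the identity.
    """
    if p.valid_mask.all():
        return p
    radius, azimuth = radial_coordinate(p.shape, centre)
    ring = np.rint(radius).astype(int)
    in_range = ring >= int(np.ceil(r_min))
    if r_max is not None:
        in_range &= ring <= int(np.floor(r_max))

    intensity = p.intensity.copy()
    valid = p.valid_mask.copy()
    nrows, ncols = p.shape

    # Pass 1: point reflection through the centre (value-preserving on
    # exactly symmetric inputs thanks to nearest-integer partner lookup).
    holes = np.nonzero(~p.valid_mask & in_range)
    if holes[0].size:
        pr = np.rint(2.0 * centre.row - holes[0]).astype(int)
        pc = np.rint(2.0 * centre.col - holes[1]).astype(int)
        inb = (pr >= 0) & (pr < nrows) & (pc >= 0) & (pc < ncols)
        ok = np.zeros(holes[0].shape, dtype=bool)
        ok[inb] = p.valid_mask[pr[inb], pc[inb]]
        intensity[holes[0][ok], holes[1][ok]] = p.intensity[pr[ok], pc[ok]]
        valid[holes[0][ok], holes[1][ok]] = True

    # Pass 2: circumferential interpolation per integer-radius ring.
    remaining = ~valid & in_range
    for r in np.unique(ring[remaining]):
        sel = ring == r
        ring_valid = valid[sel]
        if not ring_valid.any():
            logger.warning("ring at radius %d px has no valid data; left invalid", r)
            continue
        az = azimuth[sel]
        vals = intensity[sel]
        filled = vals.copy()
        filled[~ring_valid] = np.interp(
            az[~ring_valid], az[ring_valid], vals[ring_valid], period=360.0
        )
        intensity[sel] = filled
        new_valid = valid[sel]
        new_valid[:] = True
        valid[sel] = new_valid

    return p.replace(intensity=intensity, valid_mask=valid)
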