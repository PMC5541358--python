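"""Power-law diffuse background: fit in ln-ln space and subtract.

Residual scatter from the specimen cell and non-collagen components follows
I(R) = a * R**b to a good approximation over the radial range of interest.
The fit is a straight line through user-chosen anchor points of the radial
profile in double-natural-log space: b is the slope, a = exp(intercept).
With two distinct anchors the line is exact; with more it is the least-squares
fit.  Residuals after subtraction are NOT clipped at zero — clipping would
bias half-height-width measurement of weak peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .profiles import RadialProfile


@dataclass(frozen=True)
class PowerLawBackground:
    """I(R) = a * R**b with a > 0."""

    a: float
    b: float
    fit_radii: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.a > 0:
            raise ValidationError(f"amplitude a must be positive, got {self.a}")

    def evaluate(self, radius_px):
        r = np.asarray(radius_px, dtype=float)
        return self.a * np.power(r, self.b)


def fit_power_law(profile: RadialProfile, radii: Sequence[float]) -> PowerLawBackground:
    """Fit I = a*R**b through the profile bins nearest the anchor ``radii``.

    Anchors must have defined, strictly positive intensity (the fit lives in
    log space) and span at least two distinct radii.
    """
    radii = [float(r) for r in radii]
    if len(set(radii)) < 2:
        raise ValidationError("need at least 2 distinct anchor radii")
    r_used, i_used = [], []
    for r in radii:
        idx = int(np.argmin(np.abs(profile.radius_px - r)))
        rr = float(profile.radius_px[idx])
        ii = float(profile.intensity[idx])
        if not np.isfinite(ii):
            raise ValidationError(f"no data in the profile bin at R={rr:g} px")
        if ii <= 0 or rr <= 0:
            raise ValidationError(
                f"non-positive intensity/radius at anchor R={rr:g} px (I={ii:g}); "
                "log-domain fit impossible"
            )
        r_used.append(rr)
        i_used.append(ii)
    if len(set(r_used)) < 2:
        raise ValidationError("anchors collapse onto fewer than 2 distinct bins")
    slope, intercept = np.polyfit(np.log(r_used), np.log(i_used), 1)
    return PowerLawBackground(a=float(np.exp(intercept)), b=float(slope),
                              fit_radii=tuple(r_used))


def subtract_power_law(profile: RadialProfile, bg: PowerLawBackground) -> RadialProfile:
    """Subtract a*R**b per bin; empty bins stay absent, residuals unclipped.

    A bin at R = 0 (where a negative-exponent model diverges) becomes absent.
    """
    with np.errstate(divide="ignore", over="ignore"):
        model = np.where(profile.radius_px > 0,
                         bg.evaluate(np.maximum(profile.radius_px, 1e-300)), np.nan)
    return RadialProfile(
        radius_px=profile.radius_px.copy(),
        intensity=profile.intensity - model,
        n_valid=profile.n_valid.copy(),
    )
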