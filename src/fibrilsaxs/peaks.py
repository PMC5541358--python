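"""Peak detection, the cylinder (fibril) transform and structure parameters.

The equatorial integrated intensity of a fibrous collagen specimen factorizes
as I(K) = G(K) * F2(K): the interference function G(K) of the fibril lattice
times the squared scatter amplitude of a single cylinder,

    F2(K) = amplitude * [2 * J1(K*r) / (K*r)]**2,

with r the cylinder (fibril) radius and J1 the Bessel function of the first
kind (Oster-Riley normalization, F2(0) = amplitude).  F2 has maxima at
K*r = 0, 5.14, 8.42, ...; the first subsidiary maximum yields the fibril
radius, and dividing F2 out of the background-subtracted data yields the
Bessel-compensated interference function G(K), from which the shifted
interfibrillar peak is re-measured.

Structure parameters: the meridional order-n peak gives the axial D-period,
the interfibrillar peak the (first-approximation) Bragg fibril separation,
and peak height / half-height width the relative spatial-order parameter.
HHW is implemented as the FULL width between the two half-height crossings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import j1, jn_zeros

from .errors import CompensationError, PeakNotFoundError, ValidationError
from .geometry import Calibration
from .profiles import RadialProfile

logger = logging.getLogger(__name__)

#: x = K*r of the first zero of J1 (first null of the cylinder transform).
X_FIRST_NULL = float(jn_zeros(1, 1)[0])
#: x = K*r of the first and second subsidiary maxima of F2 (zeros of J2,
#: since d/dx [J1(x)/x] is proportional to -J2(x)/x).
X_FIRST_SUBSIDIARY_MAX = float(jn_zeros(2, 1)[0])   # ~5.14
X_SECOND_SUBSIDIARY_MAX = float(jn_zeros(2, 2)[0])  # ~8.42


@dataclass(frozen=True)
class PeakMeasurement:
    """One detected peak on a background-subtracted profile."""

    position_px: float
    height: float
    hhw_px: Optional[float]      # full width at half height; None if undefined
    left_px: Optional[float]     # half-height crossings
    right_px: Optional[float]

    def __post_init__(self):
        if not self.height > 0:
            raise ValidationError("peak height must be positive")
        if self.hhw_px is not None:
            if not (self.left_px < self.position_px < self.right_px):
                raise ValidationError("half-height crossings must bracket the peak")
            if not self.hhw_px > 0:
                raise ValidationError("HHW must be positive")


@dataclass(frozen=True)
class CylinderTransform:
    """F2(K) = amplitude * [2*J1(K*r)/(K*r)]**2 for a uniform solid cylinder."""

    r_nm: float
    amplitude: float = 1.0

    def __post_init__(self):
        if not (self.r_nm > 0 and self.amplitude > 0):
            raise ValidationError("cylinder radius and amplitude must be positive")

    def evaluate(self, K):
        """F2 at scattering-vector magnitude K (nm^-1); F2(0) = amplitude."""
        x = np.asarray(K, dtype=float) * self.r_nm
        return self.amplitude * _shape_sq(x)


def _shape_sq(x):
    """[2*J1(x)/x]**2 with the x -> 0 limit handled (value 1)."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = (2.0 * j1(x[nz]) / x[nz]) ** 2
    return out


def eval_cylinder_transform(model: CylinderTransform, K):
    return model.evaluate(K)


@dataclass
class StructureParams:
    """Calibrated collagen structure parameters; absent values are ``None``."""

    d_period_nm: Optional[float] = None
    fibril_diameter_nm: Optional[float] = None
    bragg_spacing_nm: Optional[float] = None
    order_param: Optional[float] = None
    bragg_spacing_comp_nm: Optional[float] = None
    order_param_comp: Optional[float] = None


def find_nearest_peak(
    profile: RadialProfile, guess_px: float, window_px: float = 15.0
) -> PeakMeasurement:
    """Locate the local maximum nearest ``guess_px`` within +/- ``window_px``.

    A local maximum is a sample strictly greater than both neighbours (the
    leftmost sample of a plateau for ties); position and height are refined by
    3-point parabolic interpolation.  HHW is the full width between the two
    half-height crossings found by linear interpolation walking outward from
    the peak; if a crossing is not reached before the profile edge (or a gap),
    ``hhw_px`` is None and the order parameter is absent downstream.
    """
    r = profile.radius_px
    y = profile.intensity
    if not (r[0] - 0.5 <= guess_px <= r[-1] + 0.5):
        raise ValidationError(f"guess {guess_px} px outside profile range")

    candidates = []
    for i in range(1, len(y) - 1):
        if abs(r[i] - guess_px) > window_px:
            continue
        if not (np.isfinite(y[i - 1]) and np.isfinite(y[i]) and np.isfinite(y[i + 1])):
            continue
        if y[i] > y[i + 1] and y[i] > y[i - 1]:
            candidates.append(i)
    if not candidates:
        raise PeakNotFoundError(
            f"no local maximum within {window_px} px of {guess_px} px"
        )
    # nearest to the guess; ties broken toward smaller radius
    candidates.sort(key=lambda i: (abs(r[i] - guess_px), r[i]))
    i = candidates[0]

    ym, y0, yp = y[i - 1], y[i], y[i + 1]
    denom = ym - 2.0 * y0 + yp
    delta = 0.0 if denom == 0 else 0.5 * (ym - yp) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = r[1] - r[0] if len(r) > 1 else 1.0
    position = float(r[i] + delta * step)
    height = float(y0 - 0.25 * (ym - yp) * delta)

    half = height / 2.0
    left = _half_crossing(r, y, i, half, direction=-1)
    right = _half_crossing(r, y, i, half, direction=+1)
    if left is None or right is None:
        return PeakMeasurement(position, height, None, None, None)
    return PeakMeasurement(position, height, float(right - left), left, right)


def _half_crossing(r, y, i_peak, half, direction) -> Optional[float]:
    """Walk outward from the peak to the first crossing of ``half``."""
    j = i_peak
    while True:
        j_next = j + direction
        if j_next < 0 or j_next >= len(y) or not np.isfinite(y[j_next]):
            return None
        if y[j_next] <= half:
            y_a, y_b = y[j], y[j_next]
            frac = (y_a - half) / (y_a - y_b)  # y_a > half >= y_b
            return float(r[j] + frac * (r[j_next] - r[j]))
        j = j_next


def order_parameter(peak: PeakMeasurement) -> Optional[float]:
    """Relative spatial-order parameter: peak height / HHW (a.u.)."""
    if peak.hhw_px is None:
        return None
    return peak.height / peak.hhw_px


def fit_cylinder_transform(
    profile: RadialProfile,
    cal: Calibration,
    r_init_nm: float,
    amp_init: Optional[float] = None,
    mode: str = "auto",
    window_px: float = 35.0,
) -> CylinderTransform:
    """Cylinder-transform model for the equatorial profile.

    mode "manual": return the model at the supplied radius/amplitude verbatim
    (the explicit-config analogue of the interactive slider adjustment).
    mode "auto": initialize from the highest bin near the expected first
    subsidiary maximum (K*r = 5.14 at ``r_init_nm``), then refine (r,
    amplitude) by bounded least squares of F2(K) against the profile within
    the window.  On failure a warning is logged and the initial (manual)
    values are retained.
    """
    if not r_init_nm > 0:
        raise ValidationError("initial cylinder radius must be positive")
    if mode not in ("manual", "auto"):
        raise ValidationError(f"unknown cylinder fit mode {mode!r}")
    if mode == "manual":
        return CylinderTransform(r_nm=r_init_nm, amplitude=amp_init or 1.0)

    k = cal.k_per_pixel
    r_expected = X_FIRST_SUBSIDIARY_MAX / (k * r_init_nm)
    sel = (
        np.isfinite(profile.intensity)
        & (np.abs(profile.radius_px - r_expected) <= window_px)
        & (profile.intensity > 0)
    )
    fallback = CylinderTransform(r_nm=r_init_nm, amplitude=amp_init or 1.0)
    if sel.sum() < 4:
        logger.warning("cylinder auto-fit: too few bins near %g px; keeping manual values",
                       r_expected)
        return fallback

    r_sel = profile.radius_px[sel]
    y_sel = profile.intensity[sel]
    i_max = int(np.argmax(y_sel))
    r_peak = float(r_sel[i_max])
    f2_sub = _shape_sq(np.array([X_FIRST_SUBSIDIARY_MAX]))[0]
    r0 = X_FIRST_SUBSIDIARY_MAX / (k * r_peak)
    amp0 = float(y_sel[i_max] / f2_sub)

    from scipy.optimize import least_squares

    def residual(params):
        r_nm, amp = params
        return amp * _shape_sq(k * r_sel * r_nm) - y_sel

    try:
        res = least_squares(
            residual,
            x0=[r0, amp0],
            bounds=([r0 / 3.0, 0.0], [r0 * 3.0, np.inf]),
            method="trf",
        )
    except Exception as exc:  # noqa: BLE001
        logger.warning("cylinder auto-fit failed (%s); keeping manual values", exc)
        return fallback
    if not res.success or not res.x[0] > 0 or not res.x[1] > 0:
        logger.warning("cylinder auto-fit did not converge; keeping manual values")
        return fallback
    return CylinderTransform(r_nm=float(res.x[0]), amplitude=float(res.x[1]))


def bessel_compensate(
    profile: RadialProfile,
    model: CylinderTransform,
    cal: Calibration,
    epsilon: float = 1e-3,
) -> RadialProfile:
    """Divide the cylinder transform out: G(K) = I(K) / F2(K).

    Bins where F2 < epsilon * max(F2) (the neighbourhoods of the J1 zeros)
    are marked undefined to avoid division blow-up.
    """
    K = cal.K(profile.radius_px)
    f2 = model.evaluate(K)
    thresh = epsilon * float(np.nanmax(f2))
    defined = (f2 >= thresh) & np.isfinite(profile.intensity)
    if not defined.any():
        raise CompensationError("all bins undefined after cylinder-transform division")
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(defined, profile.intensity / f2, np.nan)
    return RadialProfile(
        radius_px=profile.radius_px.copy(),
        intensity=g,
        n_valid=np.where(defined, profile.n_valid, 0),
    )


def compute_structure_params(
    cal: Calibration,
    meridional: Optional[PeakMeasurement] = None,
    meridional_order: int = 1,
    interfib: Optional[PeakMeasurement] = None,
    interfib_comp: Optional[PeakMeasurement] = None,
    cylinder: Optional[CylinderTransform] = None,
) -> StructureParams:
    """Calibrate measured peak positions into collagen structure parameters.

    Missing peaks leave the corresponding fields absent (None), never zero.
    """
    out = StructureParams()
    if meridional is not None:
        out.d_period_nm = cal.spacing_from_pixel(meridional.position_px, meridional_order)
    if interfib is not None:
        out.bragg_spacing_nm = cal.spacing_from_pixel(interfib.position_px, 1)
        out.order_param = order_parameter(interfib)
    if interfib_comp is not None:
        out.bragg_spacing_comp_nm = cal.spacing_from_pixel(interfib_comp.position_px, 1)
        out.order_param_comp = order_parameter(interfib_comp)
    if cylinder is not None:
        out.fibril_diameter_nm = 2.0 * cylinder.r_nm
    return out
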