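"""Synthetic fibre-scattering patterns with known ground truth.

Every pipeline stage is testable without beamline data by composing the same
physical model the analysis assumes, per pixel at radius R, azimuth phi and
scattering vector K = k_per_pixel * R:

    I = a * R**b                                        (diffuse power law)
      + [tail + h * gauss(K; K0, sigma)] * F2(K*r) * env_eq(phi)
      + sum_n  A_n * gauss(K; 2*pi*n/D, sigma_n) * env_mer(phi)

where F2 is the cylinder transform of a fibril of radius r, K0 = 2*pi/d is
the interfibrillar interference peak, the meridional orders n sit at
K = 2*pi*n/D, and the angular envelopes are 180-deg-symmetric axial von Mises
lobes, exp(kappa * (cos(2*(phi - mu)) - 1)) — the minimal model producing
"orthogonal bimodal" orientation plots.  The diffuse equatorial tail times F2
makes the first subsidiary cylinder-transform maximum visible, as in real
equatorial data.

The noiseless image is explicitly symmetrized (point-reflected pixel pairs
averaged) so order-2 rotational symmetry holds exactly in floating point;
optional Poisson sampling, detector-gap rectangles and a beamstop disc are
applied afterwards.  Noiseless generation is deterministic byte-for-byte;
Poisson runs are reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .geometry import Centre, radial_coordinate
from .patterns import Pattern
from .peaks import X_FIRST_SUBSIDIARY_MAX, _shape_sq


@dataclass(frozen=True)
class VonMisesLobe:
    """One axial (180-deg-symmetric) von Mises orientation lobe."""

    mu_deg: float
    kappa: float
    weight: float = 1.0


@dataclass
class SyntheticSpec:
    """Ground-truth description of a synthetic collagen SAXS pattern.

    Defaults describe a hydrated-tendon-like test case on a 512x512 detector:
    axial D-period 67 nm with meridional orders 1 and 3 (calibrant first order
    at 60 px), fibril radius 19.1 nm (diameter 38.2 nm) and an interfibrillar
    interference peak at d = 55 nm, on an isotropic orientation distribution.
    """

    shape: tuple[int, int] = (512, 512)
    centre: tuple[float, float] = (256.0, 256.0)
    k_per_pixel: float = 2.0 * np.pi / (67.0 * 60.0)  # nm^-1/px; 67 nm at 60 px

    # meridional Bragg orders of the axial D-period
    d_period_nm: float = 67.0
    meridional_orders: tuple[int, ...] = (1, 3)
    meridional_amplitudes: tuple[float, ...] = (1200.0, 800.0)
    meridional_sigma_px: float = 3.0
    meridional_azimuth_deg: float = 90.0
    meridional_angular_sigma_deg: float = 8.0

    # equatorial term: interference peak x cylinder transform
    fibril_radius_nm: float = 19.1
    interference_d_nm: float = 55.0
    interference_sigma_px: float = 3.0
    interference_height: float = 2500.0
    interference_tail: float = 400.0
    orientation_lobes: Optional[tuple[VonMisesLobe, ...]] = None  # None = isotropic

    # diffuse power-law background
    background_a: float = 5.0e6
    background_b: float = -1.8

    # detector imperfections and noise
    beamstop_radius_px: float = 12.0
    gaps: tuple[tuple[int, int, int, int], ...] = ()  # (row0, row1, col0, col1)
    poisson: bool = False
    seed: int = 0
    symmetrize: bool = True

    def validate(self) -> None:
        nrows, ncols = self.shape
        cr, cc = self.centre
        edge = min(cr, cc, nrows - 1 - cr, ncols - 1 - cc)
        if edge <= 0:
            raise ValidationError("centre must lie inside the detector")
        if len(self.meridional_orders) != len(self.meridional_amplitudes):
            raise ValidationError("one amplitude per meridional order required")
        for r_px, what in [
            (self.pixel_of_interference(), "interference peak"),
            (self.pixel_of_subsidiary_max(), "first subsidiary cylinder maximum"),
        ] + [
            (self.pixel_of_meridional(n), f"meridional order {n}")
            for n in self.meridional_orders
        ]:
            if r_px >= edge:
                raise ValidationError(
                    f"{what} at {r_px:.1f} px lies beyond the detector edge ({edge:.1f} px)"
                )
        if self.symmetrize and not (
            float(2 * cr).is_integer() and float(2 * cc).is_integer()
        ):
            raise ValidationError(
                "symmetrize requires the centre on the integer or half-integer grid"
            )

    # --- ground-truth pixel positions -------------------------------------
    def pixel_of_meridional(self, order: int) -> float:
        return (2.0 * np.pi * order / self.d_period_nm) / self.k_per_pixel

    def pixel_of_interference(self) -> float:
        return (2.0 * np.pi / self.interference_d_nm) / self.k_per_pixel

    def pixel_of_subsidiary_max(self) -> float:
        return X_FIRST_SUBSIDIARY_MAX / (self.k_per_pixel * self.fibril_radius_nm)

    def ground_truth(self) -> dict:
        """All planted values, for assertion against pipeline output."""
        return {
            "shape": list(self.shape),
            "centre": list(self.centre),
            "k_per_pixel": self.k_per_pixel,
            "d_period_nm": self.d_period_nm,
            "fibril_radius_nm": self.fibril_radius_nm,
            "fibril_diameter_nm": 2.0 * self.fibril_radius_nm,
            "bragg_spacing_nm": self.interference_d_nm,
            "background_a": self.background_a,
            "background_b": self.background_b,
            "meridional_pixels": {
                int(n): self.pixel_of_meridional(n) for n in self.meridional_orders
            },
            "interference_pixel": self.pixel_of_interference(),
            "subsidiary_max_pixel": self.pixel_of_subsidiary_max(),
            "orientation_lobe_azimuths_deg": (
                [lobe.mu_deg for lobe in self.orientation_lobes]
                if self.orientation_lobes else []
            ),
            "poisson": self.poisson,
            "seed": self.seed,
        }


def _axial_von_mises(az_deg, lobes: Optional[Sequence[VonMisesLobe]]):
    """180-deg-periodic angular envelope; 1 everywhere when ``lobes`` is None."""
    az = np.asarray(az_deg, dtype=float)
    if not lobes:
        return np.ones_like(az)
    env = np.zeros_like(az)
    for lobe in lobes:
        delta = np.deg2rad(2.0 * (az - lobe.mu_deg))
        env += lobe.weight * np.exp(lobe.kappa * (np.cos(delta) - 1.0))
    return env


def _angular_kappa(sigma_deg: float) -> float:
    """Axial von Mises concentration matching a Gaussian of sd ``sigma_deg``."""
    s = np.deg2rad(sigma_deg)
    return 1.0 / (4.0 * s * s)


def model_intensity(spec: SyntheticSpec, radius, azimuth) -> np.ndarray:
    """Noiseless model intensity at the given radius/azimuth coordinates."""
    radius = np.asarray(radius, dtype=float)
    K = spec.k_per_pixel * radius
    r_safe = np.maximum(radius, 1.0)
    out = spec.background_a * r_safe ** spec.background_b

    sigma_k = spec.interference_sigma_px * spec.k_per_pixel
    K0 = 2.0 * np.pi / spec.interference_d_nm
    g = spec.interference_tail + spec.interference_height * np.exp(
        -((K - K0) ** 2) / (2.0 * sigma_k * sigma_k)
    )
    out = out + g * _shape_sq(K * spec.fibril_radius_nm) * _axial_von_mises(
        azimuth, spec.orientation_lobes
    )

    mer_env = _axial_von_mises(
        azimuth,
        [VonMisesLobe(spec.meridional_azimuth_deg,
                      _angular_kappa(spec.meridional_angular_sigma_deg))],
    )
    sigma_km = spec.meridional_sigma_px * spec.k_per_pixel
    for order, amp in zip(spec.meridional_orders, spec.meridional_amplitudes):
        Kn = 2.0 * np.pi * order / spec.d_period_nm
        out = out + amp * np.exp(-((K - Kn) ** 2) / (2.0 * sigma_km * sigma_km)) * mer_env
    return out


def _symmetrize(intensity: np.ndarray, centre: tuple[float, float]) -> np.ndarray:
    """Average point-reflected pixel pairs -> bitwise-exact order-2 symmetry."""
    nrows, ncols = intensity.shape
    rows = np.arange(nrows)[:, None]
    cols = np.arange(ncols)[None, :]
    pr = np.broadcast_to(np.rint(2.0 * centre[0] - rows).astype(int), intensity.shape)
    pc = np.broadcast_to(np.rint(2.0 * centre[1] - cols).astype(int), intensity.shape)
    inb = (pr >= 0) & (pr < nrows) & (pc >= 0) & (pc < ncols)
    out = intensity.copy()
    rr, cc = np.nonzero(inb)
    out[rr, cc] = 0.5 * (intensity[rr, cc] + intensity[pr[rr, cc], pc[rr, cc]])
    return out


def generate(spec: SyntheticSpec) -> tuple[Pattern, dict]:
    """Generate a synthetic pattern and its ground-truth record."""
    spec.validate()
    centre = Centre(*spec.centre)
    radius, azimuth = radial_coordinate(spec.shape, centre)
    intensity = model_intensity(spec, radius, azimuth)
    if spec.symmetrize:
        intensity = _symmetrize(intensity, spec.centre)

    if spec.poisson:
        rng = np.random.default_rng(spec.seed)
        intensity = rng.poisson(np.clip(intensity, 0.0, None)).astype(np.float64)

    valid = np.ones(spec.shape, dtype=bool)
    if spec.beamstop_radius_px > 0:
        valid &= radius > spec.beamstop_radius_px
    for r0, r1, c0, c1 in spec.gaps:
        valid[r0:r1, c0:c1] = False

    return Pattern(intensity, valid, source="synthetic"), spec.ground_truth()


def default_analysis_config(spec: SyntheticSpec):
    """Analysis configuration a careful user would choose for ``spec``.

    Encodes the interactive judgments of the original workflow as explicit
    values: background anchors in the quietest parts of the profile (the two
    nulls of the cylinder transform, where the equatorial term vanishes, plus
    the outer edge), peak guesses near the expected reflections, an equatorial
    sector for the cylinder-transform work, and an orientation annulus
    spanning the interfibrillar peak.
    """
    from .errors import ValidationError
    from .peaks import X_FIRST_NULL
    from scipy.special import jn_zeros
    from .config import (
        AnalysisConfig,
        BackgroundConfig,
        CalibrationConfig,
        CentreConfig,
        CylinderConfig,
        MaskConfig,
        OrientationConfig,
        PeaksConfig,
        ProfilesConfig,
    )

    spec.validate()
    nrows, ncols = spec.shape
    cr, cc = spec.centre
    edge = min(cr, cc, nrows - 1 - cr, ncols - 1 - cc)
    rio = float(np.floor(edge)) - 5.0
    kr = spec.k_per_pixel * spec.fibril_radius_nm
    null1 = X_FIRST_NULL / kr
    null2 = float(jn_zeros(1, 2)[1]) / kr
    anchors = [round(null1), round(min(null2, rio - 20)), rio]
    mer_order = max(spec.meridional_orders)
    d_cal_px = spec.pixel_of_meridional(1)  # calibrant: first order of the D-period
    return AnalysisConfig(
        centre=CentreConfig(fixed=(cr, cc)),
        calibration=CalibrationConfig(peak_pixel=d_cal_px, d_nm=spec.d_period_nm),
        mask=MaskConfig(ri=max(15.0, spec.beamstop_radius_px + 3.0), rio=rio),
        background=BackgroundConfig(fit_radii=anchors),
        profiles=ProfilesConfig(equatorial_sector_half_deg=25.0,
                                equatorial_sector_azimuth_deg=0.0),
        peaks=PeaksConfig(
            meridional_guess_px=spec.pixel_of_meridional(mer_order),
            meridional_order=mer_order,
            interfib_guess_px=spec.pixel_of_interference(),
            window_px=15.0,
        ),
        cylinder=CylinderConfig(mode="auto", r_nm=0.9 * spec.fibril_radius_nm,
                                fit_window_px=35.0),
        orientation=OrientationConfig(
            r_inner=spec.pixel_of_interference() - 8.0,
            r_outer=spec.pixel_of_interference() + 8.0,
        ),
    )


@dataclass
class CalibrantSpec:
    """Isotropic ring pattern emulating a calibrant (e.g. rat-tail tendon)."""

    shape: tuple[int, int] = (512, 512)
    centre: tuple[float, float] = (256.0, 256.0)
    ring_radius_px: float = 60.0
    ring_sigma_px: float = 2.0
    ring_amplitude: float = 2000.0
    d_nm: float = 67.0  # d-spacing assigned to the ring
    background_a: float = 5.0e6
    background_b: float = -1.8
    beamstop_radius_px: float = 12.0
    poisson: bool = False
    seed: int = 0

    def ground_truth(self) -> dict:
        return {
            "centre": list(self.centre),
            "ring_radius_px": self.ring_radius_px,
            "d_nm": self.d_nm,
            "k_per_pixel": (2.0 * np.pi / self.d_nm) / self.ring_radius_px,
        }


def generate_calibrant(spec: CalibrantSpec) -> tuple[Pattern, dict]:
    """Generate a calibrant ring pattern suitable for centring + calibration."""
    centre = Centre(*spec.centre)
    radius, _ = radial_coordinate(spec.shape, centre)
    r_safe = np.maximum(radius, 1.0)
    intensity = spec.background_a * r_safe ** spec.background_b
    intensity = intensity + spec.ring_amplitude * np.exp(
        -((radius - spec.ring_radius_px) ** 2) / (2.0 * spec.ring_sigma_px ** 2)
    )
    if spec.poisson:
        rng = np.random.default_rng(spec.seed)
        intensity = rng.poisson(np.clip(intensity, 0.0, None)).astype(np.float64)
    valid = radius > spec.beamstop_radius_px
    return Pattern(intensity, valid, source="synthetic-calibrant"), spec.ground_truth()
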