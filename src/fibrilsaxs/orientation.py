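"""Preferential collagen orientation from the azimuthal scatter distribution.

The plotted quantity is the preferentially *aligned* scatter: the azimuthal
distribution of radially integrated, background-subtracted intensity minus
its minimum (the isotropic level).  The polar-plot vector length at an
azimuth is proportional to the relative number of collagen fibrils
preferentially oriented there.

Note that equatorial scatter lies perpendicular to the fibril axis: the plot
shows the SCATTER azimuth; fibril orientation is the same plot rotated by
90 deg (exposed as ``rotate90``).

Smoothing is an exactly-zero-phase low-pass: Fourier truncation of the
360-deg-periodic signal to its first ``keep_harmonics`` harmonics (an
idempotent projection that preserves the circular mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .background import PowerLawBackground
from .errors import ValidationError
from .geometry import Centre, radial_coordinate
from .patterns import Pattern, write_orientation_profile
from .profiles import integrate_azimuthal


@dataclass
class OrientationResult:
    azimuth_deg: np.ndarray
    total: np.ndarray             # background-subtracted azimuthal profile
    isotropic_level: float        # its minimum
    aligned: np.ndarray           # total - isotropic_level (>= 0, min == 0)
    smoothed_aligned: np.ndarray  # after the zero-phase low-pass


def zero_phase_lowpass(values, keep_harmonics: int = 12) -> np.ndarray:
    """Retain harmonics 0..keep of a uniformly sampled circular signal.

    Exactly zero phase shift, real output, idempotent at fixed cutoff.
    """
    if not (isinstance(keep_harmonics, (int, np.integer)) and keep_harmonics >= 0):
        raise ValidationError("keep_harmonics must be a non-negative integer")
    values = np.asarray(values, dtype=float)
    spectrum = np.fft.rfft(values)
    spectrum[keep_harmonics + 1:] = 0.0
    return np.fft.irfft(spectrum, n=len(values))


def aligned_scatter(
    p: Pattern,
    centre: Centre,
    r_inner: float,
    r_outer: float,
    bg: PowerLawBackground | None = None,
    bin_deg: float = 1.0,
    keep_harmonics: int = 12,
) -> OrientationResult:
    """Aligned azimuthal scatter over the annulus [r_inner, r_outer].

    The fitted power-law background is evaluated at each pixel's own radius
    and subtracted before the radial (mean) integration per azimuth bin; the
    azimuthal minimum (isotropic scatter) is then subtracted.  Empty azimuth
    bins, if any, are filled by circular linear interpolation before the
    minimum is taken so that smoothing stays well defined.
    """
    radius, _ = radial_coordinate(p.shape, centre)
    annulus = p.valid_mask & (radius >= r_inner) & (radius <= r_outer)
    resid = np.zeros_like(p.intensity)
    if bg is not None:
        with np.errstate(divide="ignore", over="ignore"):
            resid[annulus] = p.intensity[annulus] - bg.evaluate(
                np.maximum(radius[annulus], 1e-12)
            )
    else:
        resid[annulus] = p.intensity[annulus]
    masked = Pattern(resid, annulus, source=p.source)
    prof = integrate_azimuthal(masked, centre, r_inner, r_outer, bin_deg=bin_deg)

    total = prof.intensity.copy()
    empty = ~np.isfinite(total)
    if empty.any():
        total[empty] = np.interp(
            prof.azimuth_deg[empty], prof.azimuth_deg[~empty], total[~empty],
            period=360.0,
        )
    iso = float(total.min())
    aligned = total - iso
    smoothed = zero_phase_lowpass(aligned, keep_harmonics)
    return OrientationResult(
        azimuth_deg=prof.azimuth_deg,
        total=total,
        isotropic_level=iso,
        aligned=aligned,
        smoothed_aligned=smoothed,
    )


def write_polar_plot(
    result: OrientationResult,
    path,
    csv_path=None,
    rotate90: bool = False,
    use_smoothed: bool = True,
) -> None:
    """Save the polar vector plot (PNG/TIFF) and an optional companion CSV.

    The CSV holds exactly the plotted values (single source of truth).
    ``rotate90`` rotates scatter azimuth to fibril azimuth.
    """
    values = result.smoothed_aligned if use_smoothed else result.aligned
    values = np.clip(values, 0.0, None)
    az = result.azimuth_deg + (90.0 if rotate90 else 0.0)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta = np.deg2rad(np.append(az, az[0] + 360.0))
    rvals = np.append(values, values[0])
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    ax.plot(theta, rvals, lw=1.5)
    ax.fill(theta, rvals, alpha=0.3)
    ax.set_yticklabels([])
    ax.set_title("Aligned collagen scatter")
    try:
        fig.savefig(path, dpi=150)
    except OSError as exc:
        raise IOError(f"could not write polar plot to {path}: {exc}") from exc
    finally:
        plt.close(fig)

    if csv_path is not None:
        write_orientation_profile(result.azimuth_deg, values, csv_path)
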