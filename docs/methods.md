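# Methods

## Model and assumptions

The pipeline treats a fibrous-collagen SAXS pattern as the sum of three
contributions at pixel radius R (azimuth φ, scattering vector K):

1. a diffuse power-law background I(R) = a·R^b from the specimen cell and
   non-collagen material;
2. equatorial scatter G(K)·F²(K) from lateral fibril packing, where
   F²(K) ∝ [2·J₁(K·r)/(K·r)]² is the transform of a uniform solid cylinder
   of radius r (length ≫ radius, uniform electron density along its axis;
   Oster–Riley normalization so F²(0) equals the model amplitude), and G(K)
   is the lattice interference function whose peak gives the Bragg
   inter-fibril separation;
3. meridional Bragg orders of the axial D-period at K = 2πn/D, arced about
   the meridian.

Assumed throughout: negligible out-of-plane scattering, hence order-2
rotational symmetry of the pattern about the beam centre (the basis of the
gap-recovery step), and fibril diameters uniform enough to produce a
well-defined unimodal cylinder transform. Polydispersity, instrument
smearing and detector point-spread are not modelled. The ~1.12
liquid-packing correction to the Bragg spacing is deliberately not applied;
the reported spacing is the first-approximation value d = 2π/K_peak.

## Calibration convention

Calibration is linear in pixel radius (small-angle approximation):
K(R) = k·R with k = (2π/d_cal)/r_cal fixed by one calibrant reflection
(e.g. hydrated rat-tail tendon, 67 nm first order). Sample-to-detector
distance and wavelength never enter; only ratios of pixel positions matter.
Azimuth is 0° along +col, increasing counter-clockwise in standard image
display; the original tool's azimuth origin is unknown, so polar plots may
differ from it by a rotation/reflection. Equatorial scatter is plotted at
the *scatter* azimuth; fibril orientation is the same plot rotated 90°
(`orientation.rotate90`, default off).

## Numerical choices

- **Circle fit**: algebraic least squares (Kåsa), solved on mean-centred
  coordinates for conditioning; exact on concyclic points. Any n ≥ 3 points
  accepted (7 is the conventional default). No iterative refinement.
- **Integration**: per-bin arithmetic *mean* of valid pixels, not sum —
  means are robust to detector gaps and masks; `n_valid` is kept per bin so
  sums remain recoverable. Pixels are assigned to 1-px radial / 1° azimuthal
  bins by centre-of-pixel rounding; no area-weighted splitting.
- **Gap filling**: pass 1 uses nearest-integer point reflection through the
  centre (value-preserving on exactly symmetric inputs; bilinear lookup was
  rejected for that reason); pass 2 interpolates linearly in unwrapped
  azimuth along integer-radius rings, wrapping 360°. A fully invalid ring is
  left invalid with a warning. Idempotent.
- **Background**: straight-line fit in double-natural-log space through ≥ 2
  anchor bins; residuals are not clipped at zero (clipping would bias HHW of
  weak peaks). Stage order is fixed: negative correction → background image
  → thresholds → gap fill; thresholds-before-background-image is a
  config-level choice the format leaves open.
- **Peaks**: nearest local maximum to the guess within a ±15 px window
  (ties toward smaller radius), 3-point parabolic sub-pixel refinement
  (δ clamped to ±0.5 bin), half-height crossings by linear interpolation
  walking outward. HHW is the FULL width at half height; if the original
  tool used a half width, its absolute order parameters differ by 2×.
- **Cylinder fit** (`auto` mode): initialized from the highest bin near the
  expected first subsidiary maximum (K·r = 5.1356), then bounded least
  squares of amplitude·F² over a ±35 px window; on failure the supplied
  manual values are retained with a warning. `manual` mode uses the
  configured radius/amplitude verbatim.
- **Bessel compensation**: bins with F² < ε·max(F²) (default ε = 10⁻³) are
  marked undefined to avoid blow-up at the J₁ nulls; the compensated
  interfibrillar peak and order parameter are re-measured on the remaining
  bins.
- **Orientation smoothing**: Fourier truncation to harmonics 0..12 of the
  360°-periodic aligned profile — the simplest exactly-zero-phase,
  exactly-periodic low-pass, and an idempotent projection.

## Equatorial sector integration

With a 67 nm D-period (order 3 at K = 3·2π/67) and a 19.1 nm fibril radius
(first subsidiary maximum at K = 5.1356/19.1), the meridional third order
and the subsidiary cylinder maximum are only ~4.3 % apart in K for any
calibration. On a full-azimuth profile they overlap and bias the cylinder
fit, so `integrate_radial` accepts optional azimuthal sector limits and the
default configuration fits the cylinder transform (and measures the
interfibrillar peak) on an equatorial sector of ±25°, while the meridional
peak is measured on the full-azimuth profile. Sector integration is
standard practice for fibre patterns; the sector is configurable
(`profiles.equatorial_sector_half_deg`, unset = full azimuth).

## Synthetic generator

`SyntheticSpec` defaults describe a hydrated-tendon-like test case on a
512×512 detector, centre (256, 256), calibrant first order at 60 px:
D = 67 nm with meridional orders 1 and 3 (peak amplitudes 1200/800 counts,
radial σ 3 px, angular σ 8° about the meridian), fibril radius 19.1 nm
(diameter 38.2 nm), interference peak at d = 55 nm (height 2500, σ 3 px)
riding on a diffuse equatorial tail (400) times F², background a = 5×10⁶,
b = −1.8, beamstop of 12 px. Amplitudes and widths were chosen once on
signal-to-noise grounds: the interference σ of 3 px keeps the multiplicative
peak shift from the falling F² below 1 % of the spacing; the tail of 400
makes the first subsidiary maximum (~1.5 % of the local background) clearly
measurable under Poisson noise while perturbing the background anchors by
< 3 %; per-peak integrated counts are ≫ 10⁴ so Poisson runs are
photon-rich. Angular envelopes are axial (180°-symmetric) von Mises lobes,
exp(κ(cos 2(φ−μ)−1)), with κ = 1/(4σ²) matching a Gaussian of sd σ.

The noiseless image is symmetrized by averaging point-reflected pixel pairs,
so order-2 symmetry is exact in floating point (this is what makes the
symmetry-fill identity testable bitwise). Poisson sampling, module-gap
rectangles and the beamstop disc are applied afterwards.

`default_analysis_config(spec)` encodes the interactive judgments a careful
user would make for such a pattern: background anchors at the two nulls of
the cylinder transform (where the equatorial term vanishes) plus the outer
profile edge, peak guesses at the expected reflections, the ±25° equatorial
sector, and an orientation annulus of ±8 px about the interference peak.

What the generator does *not* emulate: form-factor polydispersity, beam
smearing, detector point-spread, flat-field structure, or spatially varying
background. Passing recovery tests therefore demonstrates correctness of
the reduction arithmetic and calibration chain on model-conforming data,
not robustness to every artefact of real beamline images.

## Problem sizes

Tests and the acceptance script run the full pipeline on 512×512 patterns
(one noiseless, one Poisson-sampled) — a realistic single-module detector
size that keeps the whole suite fast while exercising every stage at full
resolution.

## Degenerate inputs and failure behaviour

Collinear centring points, non-positive calibration values, empty
annuli/profiles, log-domain background anchors with I ≤ 0, and all-undefined
compensation raise typed errors naming the stage. A peak whose half-height
crossing runs off the profile edge yields `hhw_px = None` and an absent
order parameter rather than an error, so batches keep going; batch runs log
per-image failures and continue (CLI exit code 2 on partial failure).

## Known limitations

- Absolute order parameters depend on the HHW convention (full width here).
- The raw Bragg spacing is biased high by the falling cylinder transform;
  use the Bessel-compensated value when F² is well fitted.
- Calibration ignores tan(2θ) flattening; fine for true small-angle data,
  increasingly wrong beyond a few degrees.
- CSV (not .xlsx) output; native detector formats (CBF, HDF5/NeXus) are out
  of scope — convert to TIFF/PNG first.
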