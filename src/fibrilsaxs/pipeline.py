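"""End-to-end orchestration: single-pattern runs and semi-automated batches.

Stage order: load -> negative correction -> background image subtraction ->
threshold masking -> gap filling -> radial profile -> power-law background ->
peak detection / cylinder transform / Bessel compensation -> orientation.

Required stages (through the power-law fit) raise :class:`PipelineError` with
the stage name; optional measurement stages log their failure, mark the
results row with a ``stage:failed`` flag and leave the affected fields
absent, so a batch keeps going.

Every run writes a JSON log holding the resolved configuration and the
results; re-running from that log reproduces the outputs bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import peaks as pk
from .background import fit_power_law, subtract_power_law
from .config import AnalysisConfig
from .errors import FibrilSAXSError, PipelineError
from .geometry import Centre, fit_circle, make_calibration
from .orientation import aligned_scatter, write_polar_plot
from .patterns import (
    ResultsRow,
    load_pattern,
    write_orientation_profile,
    write_results,
)
from .preprocess import MaskSpec, apply_mask, correct_negative, fill_gaps, subtract_background_image

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".tif", ".tiff", ".png", ".jpg", ".jpeg")


def _resolve_centre(config: AnalysisConfig, shape) -> Centre:
    if config.centre.fixed is not None:
        return Centre(float(config.centre.fixed[0]), float(config.centre.fixed[1]))
    return fit_circle(config.centre.points).centre


def run_single(
    config: AnalysisConfig,
    image_path,
    out_dir=None,
) -> ResultsRow:
    """Process one pattern; optionally write all artifacts under ``out_dir``."""
    config.validate()
    image_path = Path(image_path)
    src = image_path.name
    stages: list[str] = []

    def required(stage):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:
                raise PipelineError(stage, src, str(exc)) from exc
            stages.append(stage)
            return result
        return deco

    p = required("load")(lambda: load_pattern(image_path))
    centre = required("centre")(lambda: _resolve_centre(config, p.shape))
    cal = required("calibration")(
        lambda: make_calibration(config.calibration.peak_pixel, config.calibration.d_nm)
    )

    p = required("negative_correction")(lambda: correct_negative(p))
    if config.background.image_path:
        bg_img = required("background_image")(
            lambda: load_pattern(config.background.image_path)
        )
        p = required("background_image_subtraction")(
            lambda: subtract_background_image(p, bg_img, config.background.scale)
        )
    mask_spec = MaskSpec(
        lower_limit=config.mask.ll,
        upper_limit=config.mask.ul,
        r_inner=config.mask.ri,
        r_outer=np.inf if config.mask.rio is None else config.mask.rio,
    )
    p = required("threshold_mask")(lambda: apply_mask(p, mask_spec, centre))
    p = required("gap_fill")(
        lambda: fill_gaps(p, centre, r_min=config.mask.ri,
                          r_max=config.mask.rio)
    )

    profile = required("radial_profile")(
        lambda: _radial(p, centre, config, sector=False)
    )
    bg = required("background_fit")(
        lambda: fit_power_law(profile, config.background.fit_radii)
    )
    sub = subtract_power_law(profile, bg)

    if config.profiles.equatorial_sector_half_deg:
        eq_profile = required("equatorial_profile")(
            lambda: _radial(p, centre, config, sector=True)
        )
        eq_sub = subtract_power_law(eq_profile, bg)
    else:
        eq_sub = sub

    # --- optional measurement stages --------------------------------------
    meridional = _optional(
        stages, "meridional_peak", src,
        lambda: pk.find_nearest_peak(
            sub, config.peaks.meridional_guess_px, config.peaks.window_px
        ) if config.peaks.meridional_guess_px else None,
    )
    interfib = _optional(
        stages, "interfib_peak", src,
        lambda: pk.find_nearest_peak(
            eq_sub, config.peaks.interfib_guess_px, config.peaks.window_px
        ) if config.peaks.interfib_guess_px else None,
    )
    cylinder = _optional(
        stages, "cylinder_fit", src,
        lambda: pk.fit_cylinder_transform(
            eq_sub, cal,
            r_init_nm=config.cylinder.r_nm or 0.0,
            amp_init=config.cylinder.amplitude,
            mode=config.cylinder.mode,
            window_px=config.cylinder.fit_window_px,
        ) if config.cylinder.r_nm else None,
    )
    interfib_comp = None
    if cylinder is not None and interfib is not None:
        def comp():
            g = pk.bessel_compensate(eq_sub, cylinder, cal, config.cylinder.epsilon)
            return pk.find_nearest_peak(
                g, interfib.position_px, config.peaks.window_px
            )
        interfib_comp = _optional(stages, "bessel_compensation", src, comp)

    params = pk.compute_structure_params(
        cal,
        meridional=meridional,
        meridional_order=config.peaks.meridional_order,
        interfib=interfib,
        interfib_comp=interfib_comp,
        cylinder=cylinder,
    )

    orient = None
    if config.orientation.enabled:
        orient = _optional(
            stages, "orientation", src,
            lambda: aligned_scatter(
                p, centre,
                config.orientation.r_inner, config.orientation.r_outer,
                bg=bg,
                bin_deg=config.orientation.bin_deg,
                keep_harmonics=config.orientation.keep_harmonics,
            ),
        )

    row = ResultsRow(
        source=src,
        centre_row=centre.row,
        centre_col=centre.col,
        d_period_nm=params.d_period_nm,
        fibril_diameter_nm=params.fibril_diameter_nm,
        bragg_spacing_nm=params.bragg_spacing_nm,
        order_param=params.order_param,
        bragg_spacing_comp_nm=params.bragg_spacing_comp_nm,
        order_param_comp=params.order_param_comp,
        stages=";".join(stages),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = image_path.stem
        write_results([row], out_dir / f"{stem}_results.csv")
        if orient is not None:
            write_polar_plot(
                orient,
                out_dir / f"{stem}_polar.png",
                csv_path=out_dir / f"{stem}_orientation.csv",
                rotate90=config.orientation.rotate90,
            )
        runlog = {
            "image": str(image_path),
            "config": config.to_dict(),
            "centre": [centre.row, centre.col],
            "calibration": {"r_cal": cal.r_cal, "d_cal": cal.d_cal,
                            "k_per_pixel": cal.k_per_pixel},
            "background": {"a": bg.a, "b": bg.b, "fit_radii": list(bg.fit_radii)},
            "stages": stages,
            "results": {
                k: v for k, v in row.__dict__.items() if k != "stages"
            },
        }
        with open(out_dir / f"{stem}_runlog.json", "w") as fh:
            json.dump(runlog, fh, indent=2, default=float)

    return row


def _radial(p, centre, config: AnalysisConfig, sector: bool):
    ranges = None
    if sector:
        half = config.profiles.equatorial_sector_half_deg
        mu = config.profiles.equatorial_sector_azimuth_deg
        ranges = [(mu - half, mu + half), (mu + 180.0 - half, mu + 180.0 + half)]
    from .profiles import integrate_radial

    return integrate_radial(
        p, centre,
        r_min=config.mask.ri,
        r_max=config.mask.rio,
        azimuth_ranges=ranges,
        bin_px=config.profiles.radial_bin_px,
    )


def _optional(stages, stage, src, fn):
    try:
        result = fn()
    except FibrilSAXSError as exc:
        logger.warning("[%s] %s: %s (field left absent)", stage, src, exc)
        stages.append(f"{stage}:failed")
        return None
    if result is not None:
        stages.append(stage)
    return result


def run_batch(
    config: AnalysisConfig,
    image_dir,
    out_dir=None,
) -> tuple[list[ResultsRow], list[tuple[str, str]]]:
    """Process every image in ``image_dir`` (lexicographic order) with the
    same retained parameters.  Returns (rows, failures); a failing image is
    logged and skipped.  The combined table goes to ``out_dir/results.csv``.
    """
    image_dir = Path(image_dir)
    files = sorted(
        f for f in image_dir.iterdir()
        if f.is_file() and f.suffix.lower() in IMAGE_SUFFIXES
    )
    if not files:
        raise FibrilSAXSError(f"no loadable images in {image_dir}")
    rows: list[ResultsRow] = []
    failures: list[tuple[str, str]] = []
    for f in files:
        sub_out = None if out_dir is None else Path(out_dir) / f.stem
        try:
            rows.append(run_single(config, f, out_dir=sub_out))
        except Exception as exc:  # noqa: BLE001 - batch must continue
            logger.error("batch: %s failed: %s", f.name, exc)
            failures.append((f.name, str(exc)))
    if out_dir is not None and rows:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        write_results(rows, Path(out_dir) / "results.csv")
    return rows, failures
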