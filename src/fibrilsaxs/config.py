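"""Declarative analysis configuration.

Every interactive gesture of the original workflow (clicked points, slider
values) becomes an explicit config value.  The config is a nested mapping
(YAML or JSON on disk) validated into typed dataclasses; the resolved dict is
written to the per-run JSON log so any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError


@dataclass
class CentreConfig:
    fixed: Optional[tuple[float, float]] = None        # bypass fitting
    points: Optional[list[tuple[float, float]]] = None  # ring points to fit


@dataclass
class CalibrationConfig:
    peak_pixel: float = 0.0
    d_nm: float = 0.0


@dataclass
class MaskConfig:
    ll: float = -np.inf
    ul: float = np.inf
    ri: float = 0.0
    rio: Optional[float] = None


@dataclass
class BackgroundConfig:
    image_path: Optional[str] = None
    scale: float = 1.0
    fit_radii: list[float] = field(default_factory=list)


@dataclass
class ProfilesConfig:
    radial_bin_px: float = 1.0
    azimuth_bin_deg: float = 1.0
    # optional equatorial sector (half-width about the sector azimuth and the
    # opposite azimuth); None integrates the full azimuth range
    equatorial_sector_half_deg: Optional[float] = None
    equatorial_sector_azimuth_deg: float = 0.0


@dataclass
class PeaksConfig:
    meridional_guess_px: Optional[float] = None
    meridional_order: int = 1
    interfib_guess_px: Optional[float] = None
    window_px: float = 15.0


@dataclass
class CylinderConfig:
    mode: str = "auto"  # "auto" | "manual"
    r_nm: Optional[float] = None
    amplitude: Optional[float] = None
    fit_window_px: float = 35.0
    epsilon: float = 1e-3


@dataclass
class OrientationConfig:
    enabled: bool = True
    r_inner: Optional[float] = None
    r_outer: Optional[float] = None
    bin_deg: float = 1.0
    keep_harmonics: int = 12
    rotate90: bool = False


@dataclass
class AnalysisConfig:
    centre: CentreConfig = field(default_factory=CentreConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    profiles: ProfilesConfig = field(default_factory=ProfilesConfig)
    peaks: PeaksConfig = field(default_factory=PeaksConfig)
    cylinder: CylinderConfig = field(default_factory=CylinderConfig)
    orientation: OrientationConfig = field(default_factory=OrientationConfig)

    def validate(self) -> None:
        if self.centre.fixed is None and not self.centre.points:
            raise ConfigError("centre.fixed or centre.points must be supplied")
        if self.centre.points is not None and len(self.centre.points) < 3:
            raise ConfigError("centre.points needs at least 3 points")
        if not (self.calibration.peak_pixel > 0 and self.calibration.d_nm > 0):
            raise ConfigError(
                "calibration.peak_pixel and calibration.d_nm are required and positive"
            )
        if not self.mask.ll < self.mask.ul:
            raise ConfigError("mask.ll must be < mask.ul")
        if self.mask.rio is not None and not 0 <= self.mask.ri < self.mask.rio:
            raise ConfigError("require 0 <= mask.ri < mask.rio")
        if len(self.background.fit_radii) < 2:
            raise ConfigError("background.fit_radii needs >= 2 anchor radii")
        if self.cylinder.mode not in ("auto", "manual"):
            raise ConfigError("cylinder.mode must be 'auto' or 'manual'")
        if self.cylinder.mode == "manual" and not self.cylinder.r_nm:
            raise ConfigError("cylinder.mode=manual requires cylinder.r_nm")
        if self.orientation.enabled and not (
            self.orientation.r_inner is not None
            and self.orientation.r_outer is not None
            and 0 <= self.orientation.r_inner < self.orientation.r_outer
        ):
            raise ConfigError(
                "orientation requires 0 <= r_inner < r_outer (or orientation.enabled: false)"
            )

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, float) and np.isinf(obj):
                return ".inf" if obj > 0 else "-.inf"
            return obj

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        def parse_inf(v):
            if v == ".inf":
                return np.inf
            if v == "-.inf":
                return -np.inf
            return v

        def build(dc_cls, section):
            if section is None:
                return dc_cls()
            if not isinstance(section, dict):
                raise ConfigError(f"section for {dc_cls.__name__} must be a mapping")
            names = {f.name for f in dataclasses.fields(dc_cls)}
            unknown = set(section) - names
            if unknown:
                raise ConfigError(
                    f"unknown keys {sorted(unknown)} in {dc_cls.__name__.lower()}"
                )
            kwargs = {k: parse_inf(v) for k, v in section.items()}
            return dc_cls(**kwargs)

        known = {
            "centre": CentreConfig,
            "calibration": CalibrationConfig,
            "mask": MaskConfig,
            "background": BackgroundConfig,
            "profiles": ProfilesConfig,
            "peaks": PeaksConfig,
            "cylinder": CylinderConfig,
            "orientation": OrientationConfig,
        }
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"unknown config sections {sorted(unknown)}")
        cfg = cls(**{name: build(dc, data.get(name)) for name, dc in known.items()})
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        if not path.is_file():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)
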