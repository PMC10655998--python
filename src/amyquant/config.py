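"""Validated parameter containers and config-file loading.

Two parameter sets drive the pipeline: :class:`SegmentationParams` holds
every threshold of the rule-based plaque segmentation (densities in
natural-log optical-density units, "au"; areas in square microns), and
:class:`AssayQCParams` holds the standard-curve and LOD/LLOQ acceptance
rules of the plate immunoassays.

Configuration files may be YAML or TOML with top-level sections
``segmentation``, ``assay`` and ``stain``; unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import math
import pathlib
from dataclasses import dataclass
from typing import Any, Mapping

from .errors import ConfigError


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds for tissue detection, stain classification and plaque filtering.

    Attributes
    ----------
    tissue_percentile, tissue_offset
        The tissue/glass threshold is the given brightness percentile of the
        min-channel grey raster plus ``tissue_offset`` (on the 0-255 scale).
    tissue_scale_mag, stain_scale_mag
        Nominal magnifications at which tissue detection and stain
        classification run; the slide's scan magnification divided by these
        gives the integer block-mean downsampling factors.
    brown_min_au, brown_pos_min_au
        A pixel belongs to the brown (DAB) class only if its brown density
        exceeds ``brown_min_au`` and brown-minus-blue exceeds
        ``brown_pos_min_au`` (both strict).
    dark_min_au
        Brown pixels at or above this density are "dark brown"; below, "light".
    min_area_um2, min_dark_area_um2
        Candidates smaller than ``min_area_um2``, or with less dark-brown
        area than ``min_dark_area_um2``, are removed.
    artifact_intensity_min_au, artifact_sd_max_au
        Candidates with mean brown density above the first and SD below the
        second are removed as uniform staining artifacts.
    small_area_um2, dark_fraction_max, elliptic_fit_min
        Candidates strictly smaller than ``small_area_um2`` must look
        elliptical (fit >= ``elliptic_fit_min``); candidates strictly larger
        must not exceed ``dark_fraction_max`` dark-area fraction.
    connectivity
        4 or 8; used for components and seed growing.
    """

    tissue_percentile: float = 95.0
    tissue_offset: float = -10.0
    tissue_scale_mag: int = 10
    stain_scale_mag: int = 20
    brown_min_au: float = 0.15
    brown_pos_min_au: float = 0.10
    dark_min_au: float = 0.50
    min_area_um2: float = 10.0
    min_dark_area_um2: float = 1.5
    artifact_intensity_min_au: float = 0.50
    artifact_sd_max_au: float = 0.25
    small_area_um2: float = 40.0
    dark_fraction_max: float = 0.70
    elliptic_fit_min: float = 0.65
    connectivity: int = 8

    def __post_init__(self) -> None:
        numeric = (
            self.tissue_percentile, self.tissue_offset, self.brown_min_au,
            self.brown_pos_min_au, self.dark_min_au, self.min_area_um2,
            self.min_dark_area_um2, self.artifact_intensity_min_au,
            self.artifact_sd_max_au, self.small_area_um2,
            self.dark_fraction_max, self.elliptic_fit_min,
        )
        if not all(math.isfinite(v) for v in numeric):
            raise ConfigError("segmentation thresholds must be finite")
        if not 0.0 < self.dark_fraction_max <= 1.0:
            raise ConfigError("dark_fraction_max must be in (0, 1]")
        if not self.brown_min_au < self.dark_min_au:
            raise ConfigError("brown_min_au must be below dark_min_au")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.tissue_scale_mag <= 0 or self.stain_scale_mag <= 0:
            raise ConfigError("scale magnifications must be positive")


@dataclass(frozen=True)
class AssayQCParams:
    """Standard-curve model choice and LOD/LLOQ acceptance rules.

    ``lod_sd_multiplier`` scales the blank SD in the detection limit;
    a standard passes the quantification-limit screen when its back
    interpolation lies in [``lloq_backinterp_low_pct``,
    ``lloq_backinterp_high_pct``] percent, its duplicate CV is at most
    ``lloq_cv_max_pct`` percent and its mean signal clears the blank mean by
    ``blank_sd_multiplier`` blank SDs.

    ``lod_add_blank_mean`` selects between the blank-anchored threshold
    (mean + k*SD, default) and the bare k*SD form; the latter sits below the
    blank signal itself whenever blanks are nonzero, so it is off by default.
    """

    lod_sd_multiplier: float = 2.5
    lloq_backinterp_low_pct: float = 80.0
    lloq_backinterp_high_pct: float = 120.0
    lloq_cv_max_pct: float = 20.0
    blank_sd_multiplier: float = 9.0
    curve_model: str = "4PL"
    weighting: str = "none"
    lod_add_blank_mean: bool = True

    def __post_init__(self) -> None:
        if self.lod_sd_multiplier <= 0 or self.blank_sd_multiplier <= 0:
            raise ConfigError("SD multipliers must be positive")
        if not self.lloq_backinterp_low_pct < 100.0 < self.lloq_backinterp_high_pct:
            raise ConfigError("back-interpolation band must bracket 100%")
        if self.curve_model not in ("4PL", "5PL"):
            raise ConfigError("curve_model must be '4PL' or '5PL'")
        if self.weighting not in ("none", "1/y", "1/y2"):
            raise ConfigError("weighting must be one of 'none', '1/y', '1/y2'")


def _build(cls: type, section: Mapping[str, Any], name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | pathlib.Path) -> dict[str, Any]:
    """Load a YAML/TOML config into parameter objects.

    Returns a dict with keys ``segmentation`` (:class:`SegmentationParams`),
    ``assay`` (:class:`AssayQCParams`) and ``stain`` (raw mapping, consumed
    by :class:`~amyquant.stains.StainReference`). Missing sections get
    defaults.
    """
    path = pathlib.Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    elif path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        raise ConfigError(f"unsupported config format: {path.suffix!r}")
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {"segmentation", "assay", "stain"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    return {
        "segmentation": _build(SegmentationParams, raw.get("segmentation", {}), "segmentation"),
        "assay": _build(AssayQCParams, raw.get("assay", {}), "assay"),
        "stain": dict(raw.get("stain", {})),
    }
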