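"""Run configuration with validated defaults.

Every analysis constant lives here so a run can be reproduced from the
resolved configuration file written next to its outputs.  Intensity gates
are in arbitrary detector units (ADU) and are camera-specific: the defaults
are the values used on the original instrument and must be recalibrated for
other data, including synthetic scenes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DetectionConfig(_Strict):
    """Blob-detection operating point.

    ``threshold`` is in amplitude units (ADU): the band-pass response is
    normalized so that an isolated Gaussian spot of amplitude A at the
    configured scale scores ~A.  ``split_sensitivity`` is the h-maxima depth
    used to split merged maxima; lower values split more aggressively.
    """

    scale_um: tuple[float, float, float] = (0.35, 0.13, 0.13)
    threshold: float = Field(50.0, gt=0)
    split_sensitivity: float = Field(10.0, ge=0)
    min_intensity_gate: float = Field(0.0, ge=0)

    @model_validator(mode="after")
    def _positive_scale(self):
        if any(s <= 0 for s in self.scale_um):
            raise ValueError("scale_um must be > 0 per axis")
        return self


class SegmentationConfig(_Strict):
    sharpen_radius_um: float = Field(0.3, gt=0)
    sharpen_amount: float = Field(1.0, ge=0)
    edge_sigma_um: float = Field(0.2, gt=0)
    edge_gain: float = Field(2.0, ge=0)
    seed_smooth_um: float = Field(0.4, gt=0)
    flood_smooth_um: float = Field(0.15, ge=0)
    h_minima_depth: float = Field(50.0, gt=0)
    mask_threshold: str = "otsu"          # embryo-mask threshold method
    mask_erode_vox: int = Field(1, ge=0)  # trims the blurred shell's outer half
    denoise_sigma_um: tuple[float, float, float] = (0.1, 0.05, 0.05)


class ProximityConfig(_Strict):
    cutoff_um: float = Field(0.35, gt=0)   # membrane-proximity band, inclusive
    min_spots: int = Field(25, ge=0)       # per-embryo inclusion, >= 25
    categorize_cutoff_um: float = Field(0.35, gt=0)


class ColocConfig(_Strict):
    match_radius_um: float = Field(0.26, gt=0)  # ~2 projected spot sigmas
    translation_gate: float = Field(25000.0, ge=0)  # ADU, strict >
    mrna_gate: float = Field(50000.0, ge=0)         # ADU, strict >
    min_translation_spots: int = Field(3, ge=0)     # strict >, overlap assay
    projection_slices: int = Field(6, ge=1)


class CountingConfig(_Strict):
    translation_gate: float = Field(2000.0, ge=0)   # ADU, strict >
    min_spots: int = Field(7, ge=0)                 # strict >, re-localization
    projection_slices: int = Field(5, ge=1)


class LineScanConfig(_Strict):
    width_px_membrane: int = Field(30, ge=1)   # apical membrane levels
    width_px_frap: int = Field(20, ge=1)       # bleached-region readout
    width_px_actin: int = Field(15, ge=1)      # apical actin enrichment
    n_scans: int = Field(3, ge=1)


class FrapConfig(_Strict):
    n_prebleach: int = Field(5, ge=1)
    frame_interval_s: float = Field(20.0, gt=0)
    per_animal: int = Field(2, ge=1)
    normalize_by: str = "prebleach"  # or "bleached_amount"

    @model_validator(mode="after")
    def _mode(self):
        if self.normalize_by not in ("prebleach", "bleached_amount"):
            raise ValueError("normalize_by must be prebleach|bleached_amount")
        return self


class RunConfig(_Strict):
    detection: DetectionConfig = DetectionConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    proximity: ProximityConfig = ProximityConfig()
    coloc: ColocConfig = ColocConfig()
    counting: CountingConfig = CountingConfig()
    linescan: LineScanConfig = LineScanConfig()
    frap: FrapConfig = FrapConfig()

    # filled by load_config: dotted field path -> "default"|"file"|"cli"
    provenance: dict[str, str] = Field(default_factory=dict)


def _flatten(d: dict, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out


def _set_dotted(cfg: RunConfig, dotted: str, value: Any) -> None:
    parts = dotted.split(".")
    obj: Any = cfg
    for p in parts[:-1]:
        if not hasattr(obj, p):
            raise ValueError(f"unknown config section {dotted!r}")
        obj = getattr(obj, p)
    if not hasattr(obj, parts[-1]):
        raise ValueError(f"unknown config key {dotted!r}")
    setattr(obj, parts[-1], value)


def load_config(
    path: str | Path | None = None,
    overrides: dict[str, Any] | None = None,
) -> RunConfig:
    """Resolve defaults -> file values -> overrides, in that precedence.

    ``overrides`` keys are dotted paths, e.g. ``"proximity.cutoff_um"``.
    Unknown keys and out-of-range values raise with the offending path.
    """
    cfg = RunConfig()
    prov = {k: "default" for k in _flatten(cfg.model_dump(exclude={"provenance"}))}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else {}
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        for dotted, value in _flatten(loaded).items():
            _set_dotted(cfg, dotted, value)
            prov[dotted] = "file"
    for dotted, value in (overrides or {}).items():
        _set_dotted(cfg, dotted, value)
        prov[dotted] = "cli"
    cfg.provenance = prov
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Persist the resolved configuration (with provenance) as JSON."""
    Path(path).write_text(json.dumps(cfg.model_dump(), indent=2, sort_keys=True))
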