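"""Pipeline configuration: every tunable numeric parameter in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import InputError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Resolved numeric parameters for a pipeline run.

    Defaults are the protocol constants: 20-80 HU windows for normal brain
    and baseline core, 0-40 HU for visible follow-up infarct, core rule
    CBF < 30% of Tmax<4s-normal tissue.
    """

    # NWU thresholds (HU, inclusive)
    infarct_hu: tuple[float, float] = (0.0, 40.0)
    baseline_core_hu: tuple[float, float] = (20.0, 80.0)
    normal_hu: tuple[float, float] = (20.0, 80.0)
    min_region_voxels: int = 50
    # CSF segmentation
    csf_hu_low: float = -5.0
    csf_hu_high: float = 15.0
    csf_min_component_ml: float = 0.3
    # infarct segmentation
    delta_hu: float = 1.5
    smoothing_mm: float = 2.0
    min_component_ml: float = 1.0
    # CTP
    svd_threshold_fraction: float = 0.1
    aif_k: int = 20
    cbf_core_fraction: float = 0.30
    tmax_normal_s: float = 4.0
    # brain extraction
    brain_hu_low: float = 0.0
    brain_hu_high: float = 80.0
    # reproducibility
    seed: int = 0

    _RANGES = {
        "min_region_voxels": (1, 10_000_000),
        "csf_min_component_ml": (0.0, 1e6),
        "delta_hu": (0.0, 100.0),
        "smoothing_mm": (0.0, 50.0),
        "min_component_ml": (0.0, 1e6),
        "svd_threshold_fraction": (1e-9, 0.999),
        "aif_k": (1, 100000),
        "cbf_core_fraction": (1e-9, 0.999),
        "tmax_normal_s": (1e-9, 1e6),
    }

    def __post_init__(self) -> None:
        for name in ("infarct_hu", "baseline_core_hu", "normal_hu"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InputError(f"{name} must satisfy low < high, got ({lo}, {hi})")
            setattr(self, name, (float(lo), float(hi)))
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise InputError(f"{name}={v} outside valid range [{lo}, {hi}]")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise InputError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}
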