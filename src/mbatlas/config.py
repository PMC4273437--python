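"""Pipeline configuration: one schema-versioned YAML, strict about keys.

All randomness flows from a single root seed via named substreams per stage,
so every numeric output table is reproducible from the resolved config file
archived next to the outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "load_config", "stage_seed"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    out_dir: str = "runs/default"
    standard_brain_path: str | None = None   # None -> synthesize the phantom brain

    # phantom geometry (desk scale)
    grid_shape: tuple[int, int, int] = (64, 96, 96)
    spacing_um: float = 0.76
    border_dip_factor: float = 0.4

    # specimens & registration
    n_specimens: int = 4
    expressed_types: tuple[str, ...] = ("MBON-a2sc", "MBON-b1>a", "PPL1-ap2a2")
    keep_fraction: float = 0.25
    affine_maxiter: int = 20
    registration_pyramid: tuple[int, ...] = (4, 2)
    deform_iterations: tuple[int, ...] = (10, 5)
    metric_weight: float = 0.5

    # segmentation
    gate_mean_um: float = 4.5
    gate_sd_um: float = 0.35
    t_low: float = 0.3
    t_high: float = 0.7
    n_nuclei: int = 50
    touching_fraction: float = 0.2
    enrichment_min: float = 5.0

    # quantification
    sigma_blur: float = 2.0
    cube_voxels: int = 10
    tolerance_radius_vox: float = 1.0
    k_clusters: int = 3

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema_version {self.schema_version} != {SCHEMA_VERSION}"
            )
        for name in ("grid_shape", "expressed_types", "registration_pyramid",
                     "deform_iterations"):
            setattr(self, name, tuple(getattr(self, name)))
        if not 0 < self.keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        if self.t_low >= self.t_high:
            raise ValueError("t_low must be below t_high")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path


_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected, never ignored."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - _FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


#: fixed substream ids per pipeline stage
_STAGES = ("standard", "specimen", "transform", "nuclei", "photoactivation", "qc")


def stage_seed(root_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    if stage not in _STAGES:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([root_seed, _STAGES.index(stage), index])
    return int(ss.generate_state(1)[0] % (2 ** 31))
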