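"""Run configuration with validated defaults.

Every analysis parameter has a default equal to the pipeline's documented
design defaults; unknown keys in a config file are rejected rather than
ignored, so typos cannot silently change a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    # global
    seed: int = 0
    out_dir: str = "cocscreen_out"
    alpha: float = 0.05
    comparisons: str = "all-pairs"  # or "vs-reference"
    reference_group: str | None = "vehicle"
    # mito profile
    center_fraction: float = 0.8
    aggregate_planes: bool = False
    # cytometry
    overlap_min: float = 0.5
    bg_radius_px: int = 15
    size_min_px: int | None = None
    size_max_px: int | None = None
    n_planes: int = 3
    # simulation sizes (small by default; every stage stays exercisable)
    n_oocytes: int = 3
    oocyte_true_ratio: float = 1.4
    oocyte_noise_sd: float = 5.0
    oocyte_radius_px: int = 60
    n_expansion_pairs: int = 3
    expansion_fold: float = 3.6
    n_nucleus_fields: int = 2
    nuclei_per_field: int = 120
    nucleus_frame_px: int = 384
    # optional external inputs (override simulation for the stats stage)
    counts_csv: str | None = None
    values_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ParameterError(f"{path}: unknown config keys {unknown}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        if not 0 < self.center_fraction < 1:
            raise ParameterError("center_fraction must be in (0, 1)")
        if not 0 < self.overlap_min <= 1:
            raise ParameterError("overlap_min must be in (0, 1]")
        if self.comparisons not in {"all-pairs", "vs-reference"}:
            raise ParameterError(f"unknown comparison family {self.comparisons!r}")

    def to_dict(self) -> dict:
        return asdict(self)
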