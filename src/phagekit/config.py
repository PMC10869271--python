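"""Run configuration: every pipeline constant surfaced as a named default."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Serializable configuration binding the pipeline stages together.

    Defaults reproduce the method's stated constants: susceptibility at
    iAUC >= 0.2, a 1.5 h baseline window, the 0.1..0.5 spline-parameter
    grid, ancestor exclusion for combinations, and the assay limits of
    detection.
    """

    iauc_threshold: float = 0.2
    baseline_window_h: float = 1.5
    spline_grid: list = field(default_factory=lambda: [0.1, 0.2, 0.3, 0.4, 0.5])
    kde_grid_points: int = 512
    exclude_shared_ancestor: bool = True
    cocktail_size: int = 4
    base_sizes: list = field(default_factory=list)  # empty = all admissible sizes
    eop_reduced_log10_drop: float = 1.0
    lod_phage_pfu_per_g: float = 33.0
    lod_bacteria_cfu_per_g: float = 371.0
    lod_conjugation_cfu_per_ml: float = 200.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML (JSON is valid YAML, so both parse)."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)
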