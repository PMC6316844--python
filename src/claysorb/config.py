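"""Run configuration: a key-sectioned YAML file validated against known keys.

Unknown keys are rejected rather than ignored, so typos cannot silently fall
back to defaults; every pipeline run writes the resolved configuration
snapshot next to its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]

_STAGE_KEYS = {
    "simulate": {"kind", "params"},
    "process": {"specs"},
    "normalize": {"basis", "n_grid", "tail_fraction", "reduce"},
    "fit": {"model", "c_s", "temperature"},
    "dis": {"n_domains", "split_u", "cross_section", "u_max", "smoothing_window"},
    "md": {"cutoff", "ion_cutoff", "parallel_max_tilt", "surface_axis", "min_dwell_frames"},
}
_TOP_KEYS = {"seed", "out_dir", "log_level", "stages"} | set(_STAGE_KEYS)
_VALID_STAGES = ("simulate", "process", "normalize", "fit", "dis", "md")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    stages: tuple[str, ...] = ("simulate", "process", "normalize", "fit")
    simulate: dict = field(default_factory=lambda: {"kind": "isotherm", "params": {}})
    process: dict = field(default_factory=dict)
    normalize: dict = field(default_factory=lambda: {"basis": "edge", "reduce": True})
    fit: dict = field(default_factory=lambda: {"model": "classic"})
    dis: dict = field(default_factory=lambda: {"n_domains": 2})
    md: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in _VALID_STAGES:
                raise ValueError(f"unknown stage {stage!r}; valid: {_VALID_STAGES}")
        for stage, allowed in _STAGE_KEYS.items():
            section = getattr(self, stage)
            unknown = set(section) - allowed
            if unknown:
                raise ValueError(f"unknown keys in section {stage!r}: {sorted(unknown)}")

    def resolved(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)
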