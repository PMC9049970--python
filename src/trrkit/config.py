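"""Run configuration: TOML in, lossless dict round-trip, explicit seeds."""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters steering an end-to-end simulated analysis run."""

    seed: int = 0
    n_observers: int = 3
    n_runs: int = 2
    n_voxels: int = 20
    difficulty_schedule: list = field(default_factory=lambda: ["easy", "hard"])
    # generator
    difficulty_gain: float = 1.3
    error_gain: float = 1.4
    lapse_gain: float = 2.0
    noise_sd: float = 0.2
    global_coupling: float = 0.3
    physio_coupling: float = 0.1
    # pipeline switches
    apply_percent_change: bool = False
    project_global: bool = True
    project_physio: bool = True
    project_motion: bool = True
    include_motion: bool = True
    include_physio: bool = True
    # statistics
    n_permutations: int = 10_000
    alpha: float = 0.05
    reml: bool = True
    out_dir: str = "trrkit_out"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(Path(path), "rb") as fh:
            return cls.from_dict(tomllib.load(fh))
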