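"""Run configuration: one dataclass per pipeline stage, YAML round-trip.

Unknown keys in a YAML file are rejected so typos never silently fall back
to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class EegConfig:
    low_cut: float = 0.5  # Hz; high-pass edge of the brick-wall band-pass
    high_cut: float = 40.0  # Hz
    window_s: float = 0.5  # sliding PSD window length
    step_s: float = 0.1  # window hop; 1 sample/rate reproduces point-by-point
    drop: list[str] = field(default_factory=list)  # channels removed up front
    average_ref: bool = True
    channel_mean: bool = True  # average band power across retained channels


@dataclass
class EyeConfig:
    fc_low: float = 8.0  # Hz, low-pass cutoff
    order_low: int = 101
    fc_high: float = 0.1  # Hz, drift-removal high-pass cutoff
    order_high: int = 201
    ma_window: int = 20  # samples
    lle_k: int = 12
    lle_d: int = 2
    use_lle: bool = False  # append LLE coordinates to the fused features


@dataclass
class VehicleConfig:
    window_s: float = 5.0
    step_s: float = 1.0
    speed_in_kmh: bool = False


@dataclass
class FusionConfig:
    grid_rate: float = 1.0  # Hz of the fused observation grid
    t_window: float = 1.0  # s, alignment averaging window


@dataclass
class HmmConfig:
    n_states: int = 2
    kappa: float = 1.0  # transition pseudo-count
    n_trees: int = 200
    max_depth: int = 4
    learning_rate: float = 0.1
    reg_lambda: float = 1.0  # L2 penalty weight on leaf values
    calib_folds: int = 3  # folds used to get out-of-fold scores for Platt
    seed: int = 0


@dataclass
class RunConfig:
    eeg: EegConfig = field(default_factory=EegConfig)
    eye: EyeConfig = field(default_factory=EyeConfig)
    vehicle: VehicleConfig = field(default_factory=VehicleConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    hmm: HmmConfig = field(default_factory=HmmConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for section, values in d.items():
            if section not in sections:
                raise KeyError(f"unknown config section {section!r}")
            sub = getattr(cfg, section)
            known = {f.name for f in dataclasses.fields(sub)}
            for key, value in (values or {}).items():
                if key not in known:
                    raise KeyError(f"unknown config key {section}.{key}")
                setattr(sub, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
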