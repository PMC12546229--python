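"""Pipeline configuration: every tunable constant in one place, YAML-loadable.

Defaults follow the method's published operating point: SOR k=5 / 0.1, voxel
8 mm, key ring 0.07-0.14 m, cylinder inlier-ratio gate 30%, feature gates
5 mm / 15 deg / 50 mm, basal trunk band 0.20-0.30 m, ICP overlap 90%,
completeness threshold 5 mm.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass

import numpy as np
import yaml

from .errors import ConfigError
from .matching import MatchConfig
from .register import IcpConfig


@dataclass
class PreprocessConfig:
    ground_dist_thresh: float = 0.010
    ground_band: float = 0.020
    ground_iters: int = 1000
    ground_max_tilt: float = np.deg2rad(20.0)
    sor_k: int = 5
    sor_std_mult: float = 0.1
    voxel: float = 0.008


@dataclass
class TrunkFitConfig:
    dist_thresh: float = 0.005
    n_iter: int = 5000
    max_axis_dev: float = np.deg2rad(10.0)


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    trunk: TrunkFitConfig = field(default_factory=TrunkFitConfig)
    match: MatchConfig = field(default_factory=MatchConfig)
    icp: IcpConfig = field(default_factory=IcpConfig)
    trunk_margin: float = 0.015
    completeness_thresh: float = 0.005
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for f in fields(cls):
            if f.name not in d:
                continue
            value = d[f.name]
            current = getattr(cfg, f.name)
            if is_dataclass(current):
                if not isinstance(value, dict):
                    raise ConfigError(f"config block {f.name!r} must be a mapping")
                known = {sub.name for sub in fields(current)}
                unknown = set(value) - known
                if unknown:
                    raise ConfigError(
                        f"unknown keys in {f.name!r}: {sorted(unknown)}")
                for k, v in value.items():
                    if isinstance(v, list):
                        v = tuple(v)
                    setattr(current, k, v)
            else:
                setattr(cfg, f.name, value)
        unknown = set(d) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config blocks: {sorted(unknown)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config root must be a mapping")
        return cls.from_dict(data)


def seed_sequence(seed: int, n: int = 10) -> list[int]:
    """Deterministic per-stage seeds fanned out from one top-level seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2 ** 31)) for s in state]
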