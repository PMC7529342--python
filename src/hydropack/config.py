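"""Run configuration: JSON files, defaults, and CLI-flag precedence.

A :class:`RunConfig` is a flat record of every user-tunable knob.
Values resolve with precedence defaults < config file < explicit
flags; unknown keys in a file or flag set are an error (named in the
message, not silently ignored).  Round-tripping through JSON is
lossless, and the seed in effect is always part of the record so any
run can be reproduced from its logged configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields

from .packer import AnnealSchedule
from .point_water import PointWaterParams
from .protocol import SolvateConfig


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    # explicit-water orientation grid
    angular_resolution: float = 30.0
    E_bulk: float = 1.22          # kcal/mol, stage-2 out-of-bulk cost
    # point-water potential
    E_pwat_bulk: float = 2.71     # kcal/mol, stage-1 out-of-bulk cost
    K: float = 0.52               # kcal/mol, water-water Gaussian height
    sigma: float = 0.24           # A, water-water Gaussian width
    d_ww: float = 2.7             # A, water-water optimum
    # Monte Carlo schedules (shared shape for both stages)
    RT_low: float = 0.3
    RT_high: float = 100.0
    n_cycles: int = 6
    steps_per_cycle: int | None = None
    dwell_threshold: float = 0.02
    # pipeline switches
    flexible: bool = True
    include_overlap_sites: bool = True
    # optional interface restriction / external tables
    partner_a: tuple = ()
    partner_b: tuple = ()
    tables_path: str | None = None

    def __post_init__(self):
        if not (0 <= self.seed < 2 ** 31):
            raise ConfigError("seed must be in [0, 2^31)")
        self.partner_a = tuple(self.partner_a)
        self.partner_b = tuple(self.partner_b)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["partner_a"] = list(self.partner_a)
        d["partner_b"] = list(self.partner_b)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigError(f"unknown configuration key(s): "
                              f"{', '.join(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
        if not isinstance(d, dict):
            raise ConfigError(f"configuration root in {path} must be an object")
        return cls.from_dict(d)

    # -- derived objects -----------------------------------------------
    def point_water_params(self) -> PointWaterParams:
        return PointWaterParams(K=self.K, sigma=self.sigma, d_ww=self.d_ww,
                                E_pwat_bulk=self.E_pwat_bulk)

    def schedule(self, seed_offset: int = 0) -> AnnealSchedule:
        return AnnealSchedule(RT_low=self.RT_low, RT_high=self.RT_high,
                              n_cycles=self.n_cycles,
                              steps_per_cycle=self.steps_per_cycle,
                              dwell_threshold=self.dwell_threshold,
                              seed=self.seed + seed_offset)

    def solvate_config(self) -> SolvateConfig:
        return SolvateConfig(angular_resolution=self.angular_resolution,
                             E_bulk=self.E_bulk,
                             point_water=self.point_water_params(),
                             stage1=self.schedule(0),
                             stage2=self.schedule(1),
                             flexible=self.flexible,
                             include_overlap_sites=self.include_overlap_sites,
                             seed=self.seed)


def resolve_config(file_path=None, **flags) -> RunConfig:
    """Defaults < config file < explicit flags.

    `flags` entries with value None are treated as "not given".
    Unknown keys from either source raise :class:`ConfigError`.
    """
    merged: dict = {}
    if file_path is not None:
        merged.update(RunConfig.from_json(file_path).to_dict())
    known = {f.name for f in fields(RunConfig)}
    for k, v in flags.items():
        if k not in known:
            raise ConfigError(f"unknown configuration key(s): {k}")
        if v is not None:
            merged[k] = v
    return RunConfig.from_dict(merged)
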