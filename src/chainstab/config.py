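"""Run configuration: YAML loading, validation, defaults, CSV headers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import pandas as pd
import yaml

from . import __version__

__all__ = ["RunConfig", "load_config", "dump_config", "write_records_csv", "read_records_csv"]


@dataclass
class RunConfig:
    """Everything needed to replay a full run from one master seed."""

    # ensemble
    N: int = 25
    interaction_sd: float = 0.25
    growth_low: float = 0.1
    growth_high: float = 1.0
    richness_min: int = 1
    richness_max: int = 10
    # migration grid
    rho_grid: list = field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0])
    mu_grid: list = field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0])
    # scenario sizes
    replicates: int = 60
    cycles: int = 250
    targets: int = 60
    upstream: int = 200
    # intervention grids
    sigma_grid: list = field(default_factory=lambda: [0.0, 0.05, 0.1, 0.2, 0.4, 0.8])
    m_grid: list = field(default_factory=lambda: [-0.9, -0.6, -0.3, -0.1, 0.1, 0.3, 0.6, 0.9])
    pseudo_per_m: int = 30
    # seeding / output
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("N", "replicates", "cycles", "targets", "upstream", "pseudo_per_m"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.interaction_sd <= 0:
            raise ValueError("interaction_sd must be positive")
        if not self.growth_low < self.growth_high:
            raise ValueError("growth_low must be below growth_high")
        if not 1 <= self.richness_min <= self.richness_max <= self.N:
            raise ValueError("richness range must lie within 1..N")
        for rho in self.rho_grid:
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"rho must be in [0, 1], got {rho}")
        for mu in self.mu_grid:
            if mu < 0:
                raise ValueError(f"mu must be nonnegative, got {mu}")
        for sigma in self.sigma_grid:
            if sigma < 0:
                raise ValueError(f"sigma must be nonnegative, got {sigma}")
        for m in self.m_grid:
            if not -1.0 < m < 1.0 or m == 0.0:
                raise ValueError(f"m must lie in (-1, 0) or (0, 1), got {m}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load a YAML config; missing keys get defaults, unknown keys raise."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw = {} if raw is None else raw
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def dump_config(config: RunConfig) -> dict:
    """Normalized plain-dict form (round-trips through load)."""
    return asdict(config)


def write_records_csv(df: pd.DataFrame, path, config: RunConfig | None = None, **meta) -> None:
    """Write a tidy CSV with a replay header comment block."""
    with open(path, "w") as fh:
        fh.write(f"# chainstab version: {__version__}\n")
        if config is not None:
            fh.write(f"# config hash: {config.config_hash()}\n")
            fh.write(f"# master seed: {config.seed}\n")
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
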