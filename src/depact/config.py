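"""Run configuration: a single YAML file per run, strictly validated.

Unknown keys are rejected (typos like ``speeed`` fail loudly), all units are
SI, and every stochastic stage draws from an explicit seed.  The fully
resolved configuration (defaults filled in) is echoed next to the outputs by
the pipeline commands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict, is_dataclass
from pathlib import Path

import yaml


@dataclass
class GridConfig:
    shape: list = field(default_factory=lambda: [128, 128])
    spacing: float = 0.5e-3          # m
    origin: list | None = None       # default: centered on the origin


@dataclass
class SkullConfig:
    rho: float = 1850.0              # kg/m^3
    cp: float = 2800.0               # m/s
    cs: float = 1250.0               # m/s
    inner_radius: float = 15e-3      # m
    thickness: float = 6.5e-3        # m
    tilt: float = 0.0                # rad
    center: list = field(default_factory=lambda: [0.0, 0.0])


@dataclass
class MediumConfig:
    skull: SkullConfig = field(default_factory=SkullConfig)
    water_rho: float = 1000.0        # kg/m^3
    water_temperature_c: float = 20.0


@dataclass
class SensorsConfig:
    kind: str = "circle"             # circle | hemisphere
    radius: float = 25e-3            # m
    n_elements: int = 256            # per arc for the hemisphere
    n_arcs: int = 4
    n_rotations: int = 100


@dataclass
class PMLBlock:
    thickness: int = 10
    profile_order: int = 4


@dataclass
class SolverConfig:
    dt: float = 50e-9                # s
    nt: int = 800
    pml: PMLBlock = field(default_factory=PMLBlock)


@dataclass
class ReconBlock:
    method: str = "iterative"        # ubp | adjoint | iterative
    l1_weight: float = 0.0
    tv_weight: float = 0.0
    n_outer: int = 10
    n_inner_tv: int = 20
    step_safety: float = 0.9
    power_iters: int = 20
    nonneg: bool = True
    filter_fc: float = 0.5e6         # Hz; <= 0 disables the low-pass in S
    filter_order: int = 2


@dataclass
class PhantomBlock:
    kind: str = "tubes"
    thickness: float = 1.5e-3        # m
    extent: float = 16e-3            # m
    n_segments: int = 5


@dataclass
class SeedsConfig:
    master: int = 7
    noise: int = 8
    background: int = 9


@dataclass
class PathsConfig:
    out_dir: str = "depact_out"


@dataclass
class RunConfig:
    grid: GridConfig = field(default_factory=GridConfig)
    medium: MediumConfig = field(default_factory=MediumConfig)
    sensors: SensorsConfig = field(default_factory=SensorsConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    recon: ReconBlock = field(default_factory=ReconBlock)
    phantom: PhantomBlock = field(default_factory=PhantomBlock)
    noise_rel: float = 0.01
    background_strength: float = 0.0
    seeds: SeedsConfig = field(default_factory=SeedsConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)


def _from_mapping(cls, mapping, path="config"):
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, dict):
        raise ValueError(f"{path}: expected a mapping, got {type(mapping).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(mapping) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, f in known.items():
        if name not in mapping:
            continue
        val = mapping[name]
        if is_dataclass(f.type) or (isinstance(f.type, str) and f.type in _NESTED):
            sub = _NESTED[f.type] if isinstance(f.type, str) else f.type
            kwargs[name] = _from_mapping(sub, val, f"{path}.{name}")
        else:
            kwargs[name] = val
    return cls(**kwargs)


_NESTED = {c.__name__: c for c in (
    GridConfig, SkullConfig, MediumConfig, SensorsConfig, PMLBlock,
    SolverConfig, ReconBlock, PhantomBlock, SeedsConfig, PathsConfig)}


def _validate(cfg: RunConfig) -> None:
    if cfg.solver.dt <= 0 or cfg.solver.dt > 1.0:
        raise ValueError(f"solver.dt = {cfg.solver.dt} s is not a plausible "
                         "sampling step (must be in (0, 1] s)")
    if cfg.solver.nt < 2:
        raise ValueError("solver.nt must be at least 2")
    if cfg.grid.spacing <= 0 or cfg.grid.spacing > 0.1:
        raise ValueError(f"grid.spacing = {cfg.grid.spacing} m is implausible")
    if cfg.sensors.kind not in ("circle", "hemisphere"):
        raise ValueError(f"sensors.kind must be circle|hemisphere, got {cfg.sensors.kind!r}")
    if cfg.recon.method not in ("ubp", "adjoint", "iterative"):
        raise ValueError(f"recon.method must be ubp|adjoint|iterative, got {cfg.recon.method!r}")
    if cfg.recon.l1_weight < 0 or cfg.recon.tv_weight < 0:
        raise ValueError("regularizer weights must be nonnegative")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration, filling in defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text())
    cfg = _from_mapping(RunConfig, raw)
    _validate(cfg)
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration as YAML (round-trip safe)."""
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
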