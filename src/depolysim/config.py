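"""Structured run configuration: YAML loading, validation, defaults.

A configuration file is a nested mapping with a ``scenario`` key and
optional sections; unknown keys anywhere are rejected with an error that
names the offending key.  The fully resolved configuration (defaults
applied) is serialized alongside every output so a run can be reproduced
from its artifacts.

Example::

    scenario: wellmixed
    substrate: {M: 300, n: 500}
    metabolism: {fr_exo: 0.8}
    run: {seed: 0}
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .params import KineticParams, MetabolicParams, SpatialConfig, ValidationError
from .scenarios import GrowthConfig

__all__ = ["SimConfig", "load_config", "resolve_config"]

SCENARIOS = ("enzyme_only", "wellmixed", "scan_fr", "niche_map", "spatial", "consortium")


@dataclass
class ScanSection:
    """Settings of the fr_exo degradation scan."""

    E_total: float = 3.0
    frexo_grid: list[float] = field(default_factory=lambda: [round(0.05 * i, 2) for i in range(21)])

    def __post_init__(self) -> None:
        if self.E_total <= 0:
            raise ValidationError("E_total must be > 0")
        for fr in self.frexo_grid:
            if not 0.0 <= fr <= 1.0:
                raise ValidationError(f"frexo_grid entry {fr!r} out of [0, 1]")


@dataclass
class NicheSection:
    """Grids of the niche map scenario."""

    M_grid: list[float] = field(default_factory=lambda: [150.0, 300.0, 500.0, 1000.0, 1500.0])
    frexo_grid: list[float] = field(default_factory=lambda: [0.0, 0.2, 0.5, 0.8, 1.0])


@dataclass
class EnzymeSection:
    """Fixed enzyme pool of the enzyme-only scenario."""

    E_exo: float = 0.0
    E_endo: float = 0.0

    def __post_init__(self) -> None:
        if self.E_exo < 0 or self.E_endo < 0:
            raise ValidationError("enzyme concentrations must be >= 0")


@dataclass
class RunSection:
    """Run orchestration: seed, horizon and output naming."""

    seed: int = 0
    t_end: float | None = None
    out: str = "out"
    record_every: float = 1.0
    colonists_per_taxon: int = 4
    C_b0: float = 10.0
    E_seed: float = 1.0
    DIN0: float = 200.0

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValidationError("seed must be >= 0")


@dataclass
class SubstrateSection:
    M: float = 300.0
    n: int = 500

    def __post_init__(self) -> None:
        if self.M <= 0 or self.n < 1:
            raise ValidationError("substrate requires M > 0 and n >= 1")


@dataclass
class SimConfig:
    """Fully resolved simulation configuration."""

    scenario: str
    substrate: SubstrateSection
    kinetics: KineticParams
    metabolism: MetabolicParams
    growth: GrowthConfig
    spatial: SpatialConfig
    enzymes: EnzymeSection
    scan: ScanSection
    niche: NicheSection
    run: RunSection

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"scenario": self.scenario}
        for name in ("substrate", "kinetics", "metabolism", "growth",
                     "spatial", "enzymes", "scan", "niche", "run"):
            out[name] = dataclasses.asdict(getattr(self, name))
        return out


_SECTIONS = {
    "substrate": SubstrateSection,
    "kinetics": KineticParams,
    "metabolism": MetabolicParams,
    "growth": GrowthConfig,
    "spatial": SpatialConfig,
    "enzymes": EnzymeSection,
    "scan": ScanSection,
    "niche": NicheSection,
    "run": RunSection,
}


def _build_section(name: str, cls, data: dict) -> Any:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(
            f"unknown key(s) {sorted(unknown)} in section '{name}' "
            f"(allowed: {sorted(allowed)})"
        )
    try:
        return cls(**data)
    except ValidationError as exc:
        raise ValidationError(f"section '{name}': {exc}") from exc
    except TypeError as exc:
        raise ValidationError(f"section '{name}': {exc}") from exc


def resolve_config(raw: dict) -> SimConfig:
    """Validate a raw mapping and apply defaults for absent sections."""
    if not isinstance(raw, dict):
        raise ValidationError("configuration must be a mapping")
    raw = dict(raw)
    scenario = raw.pop("scenario", None)
    if scenario not in SCENARIOS:
        raise ValidationError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    sections: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        data = raw.pop(name, {})
        if not isinstance(data, dict):
            raise ValidationError(f"section '{name}' must be a mapping")
        sections[name] = _build_section(name, cls, data)
    if raw:
        raise ValidationError(f"unknown top-level key(s) {sorted(raw)}")
    cfg = SimConfig(scenario=scenario, **sections)
    # growth substrate mirrors the substrate section unless set explicitly
    cfg.growth.M = cfg.substrate.M
    cfg.growth.n = cfg.substrate.n
    if cfg.run.t_end is not None:
        cfg.growth.t_end = float(cfg.run.t_end)
    return cfg


def load_config(path: str | Path) -> SimConfig:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"configuration file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return resolve_config(raw)
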