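"""Scenario configuration: JSON schema, unit normalization, (de)serialization.

Concentration-valued fields accept either a plain number (molar) or a string
with a unit, e.g. ``"1 nM"``, ``"10 uM"``, ``"1e-4 M"``; rate fields accept a
number (per second) or ``"40/min"``.  Molecule totals are copies per cell.
Validation reports every offending field at once (pydantic) and
cross-references (cognate sigma, repressor labels) are resolved at load time.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Any

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigError
from .scenario import Scenario
from .species import (CorePool, NonSpecificParams, PromoterClass, SigmaSpecies,
                      DEFAULT_KD_CORE, DEFAULT_KD_NS)
from .units import DEFAULT_NS_SITES, CellContext

log = logging.getLogger("sigmacomp")

_CONC_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6,
               "nm": 1e-9, "pm": 1e-12, "fm": 1e-15}
_RATE_UNITS = {"/s": 1.0, "/sec": 1.0, "/min": 1.0 / 60.0, "/h": 1.0 / 3600.0}


def parse_concentration(value: Any, field: str = "") -> float:
    """Molar value from a number or a '<number> <unit>' string."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*([a-zA-Zµ]+)\s*", str(value))
    if m and m.group(2).lower() in _CONC_UNITS:
        return float(m.group(1)) * _CONC_UNITS[m.group(2).lower()]
    raise ConfigError(f"unknown concentration unit in {field or 'field'}: {value!r}")


def parse_rate(value: Any, field: str = "") -> float:
    """Per-second value from a number or a '<number>/<time unit>' string."""
    if isinstance(value, (int, float)):
        return float(value)
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*(/\s*\w+)\s*", str(value))
    if m:
        unit = m.group(2).replace(" ", "").lower()
        if unit in _RATE_UNITS:
            return float(m.group(1)) * _RATE_UNITS[unit]
    raise ConfigError(f"unknown rate unit in {field or 'field'}: {value!r}")


class ContextConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    volume_fl: float = 1.32
    ns_sites: float = DEFAULT_NS_SITES
    unit_mode: str = "counts"

    def build(self) -> CellContext:
        return CellContext(volume_fl=self.volume_fl, ns_sites=self.ns_sites,
                           unit_mode=self.unit_mode)


class SpeciesConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    total: float = Field(ge=0)
    kd_core: float | str = DEFAULT_KD_CORE
    kon_core: float | None = None
    kd_ns_holo: float | str = DEFAULT_KD_NS
    anti_total: float = Field(default=0.0, ge=0)
    kd_anti: float | str | None = None

    def build(self) -> SigmaSpecies:
        return SigmaSpecies(
            name=self.name, total=self.total,
            kd_core=parse_concentration(self.kd_core, f"species[{self.name}].kd_core"),
            kon_core=self.kon_core,
            kd_ns_holo=parse_concentration(self.kd_ns_holo,
                                           f"species[{self.name}].kd_ns_holo"),
            anti_total=self.anti_total,
            kd_anti=(None if self.kd_anti is None else
                     parse_concentration(self.kd_anti, f"species[{self.name}].kd_anti")))


class CoreConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    total: float = Field(ge=0)
    kd_ns_core: float | str = DEFAULT_KD_NS

    def build(self) -> CorePool:
        return CorePool(total=self.total,
                        kd_ns_core=parse_concentration(self.kd_ns_core,
                                                       "core.kd_ns_core"))


class PromoterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    cognate_sigma: str
    count: float = Field(default=200.0, ge=0)
    km: float | str = 1e-9
    kmax: float | str = "40/min"
    operon_length: float = 2000.0
    retention_length: float = 300.0
    elongation_speed: float = 55.0
    release_mode: str = "separate_release"
    repressors: list[tuple[str, float | str]] = Field(default_factory=list)

    def build(self) -> PromoterClass:
        return PromoterClass(
            name=self.name, cognate_sigma=self.cognate_sigma, count=self.count,
            km=parse_concentration(self.km, f"promoter[{self.name}].km"),
            kmax=parse_rate(self.kmax, f"promoter[{self.name}].kmax"),
            operon_length=self.operon_length,
            retention_length=self.retention_length,
            elongation_speed=self.elongation_speed,
            release_mode=self.release_mode,
            repressors=tuple((label, parse_concentration(kd, "repressor kd"))
                             for label, kd in self.repressors))


class NSConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kd_ns_core: float | str = DEFAULT_KD_NS
    kd_ns_holo: dict[str, float | str] = Field(default_factory=dict)

    def build(self) -> NonSpecificParams:
        return NonSpecificParams(
            kd_ns_core=parse_concentration(self.kd_ns_core, "ns.kd_ns_core"),
            kd_ns_holo={name: parse_concentration(v, f"ns.kd_ns_holo[{name}]")
                        for name, v in self.kd_ns_holo.items()})


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start: float = Field(gt=0)
    stop: float = Field(gt=0)
    num: int = Field(default=200, ge=1)
    log: bool = True

    def build(self):
        import numpy as np
        if self.num == 1:
            return np.array([self.start])
        if self.log:
            return np.geomspace(self.start, self.stop, self.num)
        return np.linspace(self.start, self.stop, self.num)


class ScanDirective(BaseModel):
    model_config = ConfigDict(extra="forbid")
    control: str
    grid: GridConfig


class OnsetDirective(BaseModel):
    model_config = ConfigDict(extra="forbid")
    control: str
    reference_value: float = 0.0
    reference_species: str | None = None
    threshold: float = 0.05
    grid: GridConfig | None = None


class ResponseDirective(BaseModel):
    model_config = ConfigDict(extra="forbid")
    control: str
    promoter: str | None = None
    grid: GridConfig


class ScenarioConfig(BaseModel):
    """Top-level scenario configuration."""

    model_config = ConfigDict(extra="forbid")
    context: ContextConfig = Field(default_factory=ContextConfig)
    core: CoreConfig
    species: list[SpeciesConfig] = Field(min_length=1)
    promoters: list[PromoterConfig] = Field(default_factory=list)
    ns: NSConfig | None = None
    model: str = "free"
    scan: ScanDirective | None = None
    onset: OnsetDirective | None = None
    response: ResponseDirective | None = None
    seed: int = 0

    def to_scenario(self) -> Scenario:
        try:
            return Scenario(
                species=tuple(sp.build() for sp in self.species),
                core=self.core.build(),
                context=self.context.build(),
                promoters=tuple(p.build() for p in self.promoters),
                ns=self.ns.build() if self.ns is not None else None,
                model=self.model)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> ScenarioConfig:
    """Read, validate and unit-normalize a JSON scenario configuration.

    Raises :class:`ConfigError` listing every schema violation; logs the
    fields for which Table-style defaults were applied.
    """
    path = Path(path)
    raw = json.loads(path.read_text())
    try:
        cfg = ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        issues = "; ".join(
            f"{'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}"
            for err in exc.errors())
        raise ConfigError(f"invalid configuration {path}: {issues}") from exc
    cfg.to_scenario()  # resolve cross-references and units eagerly
    defaulted = sorted(set(ScenarioConfig.model_fields) - set(raw))
    if defaulted:
        log.info("defaults applied for: %s", ", ".join(defaulted))
    return cfg


def save_config(cfg: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(cfg.model_dump_json(indent=2, exclude_none=True) + "\n")
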