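"""Scenario: a complete model configuration that knows how to solve itself.

A scenario bundles the cell context, core pool, sigma species, promoter
classes and non-specific binding parameters with a model level:

* ``"free"``  — binding competition only (no DNA);
* ``"ns"``    — plus non-specific DNA binding;
* ``"cycle"`` — plus promoter occupancy and transcript elongation feedback.

Promoter classes may be attached at any level; below ``"cycle"`` they are
used only to translate solved holoenzyme levels into transcription rates
(transcription is assumed not to perturb the pools, as in vitro).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .cycle import solve_cycle
from .equilibrium import solve_free_binding, solve_with_ns
from .errors import ConfigError, UsageError
from .species import (CorePool, EquilibriumState, NonSpecificParams,
                      PromoterClass, SigmaSpecies)
from .transcription import normalized_rate, occupancy
from .units import CellContext

MODEL_LEVELS = ("free", "ns", "cycle")


@dataclass(frozen=True)
class Scenario:
    species: tuple[SigmaSpecies, ...]
    core: CorePool
    context: CellContext = field(default_factory=CellContext)
    promoters: tuple[PromoterClass, ...] = ()
    ns: NonSpecificParams | None = None
    model: str = "free"

    def __post_init__(self) -> None:
        if self.model not in MODEL_LEVELS:
            raise ConfigError(f"model must be one of {MODEL_LEVELS}, got {self.model!r}")
        names = {sp.name for sp in self.species}
        for prm in self.promoters:
            if prm.cognate_sigma not in names:
                raise ConfigError(
                    f"promoter {prm.name!r}: cognate sigma {prm.cognate_sigma!r} "
                    f"does not name a configured species")
            for label, _ in prm.repressors:
                if label not in names:
                    raise ConfigError(
                        f"promoter {prm.name!r}: repressor {label!r} does not "
                        f"name a configured species")
        if self.model == "ns" and self.ns is None:
            object.__setattr__(self, "ns", NonSpecificParams())

    def solve(self) -> EquilibriumState:
        if self.model == "free":
            return solve_free_binding(self.species, self.core, self.context)
        if self.model == "ns":
            return solve_with_ns(self.species, self.core, self.ns, self.context)
        return solve_cycle(self.species, self.core, self.promoters,
                           self.ns, self.context)

    # -- control handling for parameter scans ---------------------------------

    def control_value(self, control: str) -> float:
        if control == "core":
            return self.core.total
        for sp in self.species:
            if sp.name == control:
                return sp.total
        raise UsageError(
            f"control {control!r} names neither 'core' nor a species total "
            f"({[sp.name for sp in self.species]})")

    def with_control(self, control: str, value: float) -> "Scenario":
        """A copy of the scenario with the named total replaced."""
        if control == "core":
            return replace(self, core=replace(self.core, total=value))
        if control in {sp.name for sp in self.species}:
            new = tuple(replace(sp, total=value) if sp.name == control else sp
                        for sp in self.species)
            return replace(self, species=new)
        raise UsageError(
            f"control {control!r} names neither 'core' nor a species total")

    def promoter(self, name: str) -> PromoterClass:
        for prm in self.promoters:
            if prm.name == name:
                return prm
        raise UsageError(f"no promoter class named {name!r} in scenario")

    def normalized_rates(self, state: EquilibriumState) -> dict[str, float]:
        """Normalized transcription rate of every promoter class at a solved state."""
        holo = {n: state.free_holo_molar(n) for n in state.species_names}
        out = {}
        for prm in self.promoters:
            h = holo[prm.cognate_sigma]
            if prm.repressors:
                out[prm.name] = occupancy(h, prm, holo)
            else:
                out[prm.name] = normalized_rate(h, prm)
        return out
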