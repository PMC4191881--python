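"""Domain types: molecular species, promoter classes and solved states.

Totals are copies per cell (the unit the experimental literature reports);
all dissociation constants and Michaelis constants are molar.  Solved states
(:class:`EquilibriumState`, :class:`CycleState`) store pools as copies per
cell together with the :class:`~sigmacomp.units.CellContext` used to solve
them, so they can be reported in either unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import DomainError, check_nonnegative, check_positive
from .units import CellContext

#: Default sigma-core dissociation constant (molar); both species in the
#: two-sigma reference scenario bind core with 1 nM affinity.
DEFAULT_KD_CORE = 1e-9
#: Default non-specific dissociation constant for cores and holoenzymes (molar).
DEFAULT_KD_NS = 1e-4


@dataclass(frozen=True)
class SigmaSpecies:
    """One sigma factor species: totals and binding constants.

    ``kon_core`` (the sigma-core association rate, /M/s) is only needed when
    effective dissociation constants are computed for the transcription cycle.
    ``anti_total``/``kd_anti`` describe an optional cognate anti-sigma factor.
    """

    name: str
    total: float
    kd_core: float = DEFAULT_KD_CORE
    kon_core: float | None = None
    kd_ns_holo: float = DEFAULT_KD_NS
    anti_total: float = 0.0
    kd_anti: float | None = None

    def __post_init__(self) -> None:
        check_nonnegative(total=self.total, anti_total=self.anti_total)
        check_positive(kd_core=self.kd_core, kd_ns_holo=self.kd_ns_holo)
        if self.kon_core is not None:
            check_positive(kon_core=self.kon_core)
        if self.anti_total > 0 and self.kd_anti is None:
            raise DomainError(f"species {self.name!r}: anti_total > 0 requires kd_anti")
        if self.kd_anti is not None:
            check_positive(kd_anti=self.kd_anti)


@dataclass(frozen=True)
class CorePool:
    """The core RNA polymerase pool shared by all sigma species."""

    total: float
    kd_ns_core: float = DEFAULT_KD_NS

    def __post_init__(self) -> None:
        check_nonnegative(total=self.total)
        check_positive(kd_ns_core=self.kd_ns_core)


@dataclass(frozen=True)
class NonSpecificParams:
    """Non-specific DNA binding constants (molar) for core and each holoenzyme.

    ``kd_ns_holo`` maps species name to the holoenzyme's non-specific
    dissociation constant; species absent from the map fall back to their own
    ``kd_ns_holo`` attribute.
    """

    kd_ns_core: float = DEFAULT_KD_NS
    kd_ns_holo: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_positive(kd_ns_core=self.kd_ns_core)
        for name, kd in self.kd_ns_holo.items():
            if not kd > 0:
                raise DomainError(f"kd_ns_holo[{name!r}] must be > 0, got {kd!r}")

    def holo_kd(self, species: SigmaSpecies) -> float:
        return self.kd_ns_holo.get(species.name, species.kd_ns_holo)


RELEASE_MODES = ("holoenzyme_release", "separate_release")


@dataclass(frozen=True)
class PromoterClass:
    """A class of identical promoters cognate to one sigma species.

    Initiation is Michaelis-Menten in the free cognate holoenzyme
    concentration with maximal rate ``kmax`` (per second, per promoter) and
    Michaelis constant ``km`` (molar).  ``release_mode`` selects whether core
    and sigma leave the transcription cycle together as holoenzyme
    (``holoenzyme_release``) or separately, sigma after ``retention_length``
    nucleotides and core at the operon terminator (``separate_release``).
    ``repressors`` lists (holoenzyme species label, kd) pairs for
    non-transcribing holoenzymes that occlude this promoter.
    """

    name: str
    cognate_sigma: str
    count: float = 200.0
    km: float = 1e-9
    kmax: float = 40.0 / 60.0
    operon_length: float = 2000.0
    retention_length: float = 300.0
    elongation_speed: float = 55.0
    release_mode: str = "separate_release"
    repressors: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        check_nonnegative(count=self.count, kmax=self.kmax)
        check_positive(km=self.km, operon_length=self.operon_length,
                       retention_length=self.retention_length,
                       elongation_speed=self.elongation_speed)
        if self.retention_length > self.operon_length:
            raise DomainError(
                f"promoter {self.name!r}: retention_length ({self.retention_length}) "
                f"must not exceed operon_length ({self.operon_length})")
        if self.release_mode not in RELEASE_MODES:
            raise DomainError(
                f"promoter {self.name!r}: release_mode must be one of {RELEASE_MODES}, "
                f"got {self.release_mode!r}")
        for label, kd in self.repressors:
            if not kd > 0:
                raise DomainError(f"promoter {self.name!r}: repressor {label!r} kd must be > 0")


@dataclass(frozen=True)
class SpeciesPools:
    """Solved pools for one sigma species, copies per cell."""

    free_sigma: float
    free_holo: float
    ns_bound_holo: float = 0.0
    promoter_bound_holo: float = 0.0
    elongating_cores: float = 0.0
    retained_sigmas: float = 0.0
    anti_bound_sigma: float = 0.0

    @property
    def total_holo(self) -> float:
        """Free plus non-specifically bound holoenzymes (cytoplasmic + DNA)."""
        return self.free_holo + self.ns_bound_holo

    @property
    def sigma_sum(self) -> float:
        """All sigma-containing pools for this species."""
        return (self.free_sigma + self.free_holo + self.ns_bound_holo
                + self.promoter_bound_holo + self.retained_sigmas
                + self.anti_bound_sigma)

    @property
    def core_sum(self) -> float:
        """All core-containing pools attributable to this species."""
        return (self.free_holo + self.ns_bound_holo + self.promoter_bound_holo
                + self.elongating_cores)


@dataclass(frozen=True)
class EquilibriumState:
    """Solved partition of cores and sigma factors over all pools.

    Pools are copies per cell; ``effective_kd`` is molar.  ``residuals`` maps
    each conservation law ("core" and one entry per sigma species) to its
    relative violation.
    """

    species_names: tuple[str, ...]
    pools: dict[str, SpeciesPools]
    free_core: float
    ns_bound_core: float
    effective_kd: dict[str, float]
    context: CellContext
    residuals: dict[str, float]
    iterations: int
    converged: bool

    def __getitem__(self, name: str) -> SpeciesPools:
        return self.pools[name]

    @property
    def total_free_holo(self) -> float:
        return sum(p.free_holo for p in self.pools.values())

    def free_holo_molar(self, name: str) -> float:
        return self.context.counts_to_molar(self.pools[name].free_holo)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (species, pool)."""
        rows = []
        to_unit = (self.context.counts_to_molar
                   if self.context.unit_mode == "molar" else (lambda x: x))
        for name in self.species_names:
            p = self.pools[name]
            for pool in ("free_sigma", "free_holo", "ns_bound_holo",
                         "promoter_bound_holo", "elongating_cores",
                         "retained_sigmas", "anti_bound_sigma"):
                rows.append({"species": name, "pool": pool,
                             "value": to_unit(getattr(p, pool)),
                             "unit": self.context.unit_mode})
        for pool, value in (("free_core", self.free_core),
                            ("ns_bound_core", self.ns_bound_core)):
            rows.append({"species": "(core)", "pool": pool,
                         "value": to_unit(value), "unit": self.context.unit_mode})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "species": {
                name: {
                    "free_sigma": p.free_sigma,
                    "free_holo": p.free_holo,
                    "ns_bound_holo": p.ns_bound_holo,
                    "promoter_bound_holo": p.promoter_bound_holo,
                    "elongating_cores": p.elongating_cores,
                    "retained_sigmas": p.retained_sigmas,
                    "anti_bound_sigma": p.anti_bound_sigma,
                    "effective_kd": self.effective_kd[name],
                }
                for name, p in self.pools.items()
            },
            "free_core": self.free_core,
            "ns_bound_core": self.ns_bound_core,
            "unit": "counts",
            "diagnostics": {
                "residuals": dict(self.residuals),
                "iterations": self.iterations,
                "converged": self.converged,
            },
        }


@dataclass(frozen=True)
class PromoterState:
    """Per-promoter-class steady-state quantities of the transcription cycle."""

    name: str
    occupancy: float                  # fraction of promoters holoenzyme-bound
    bound_holo: float                 # occupancy * count, copies per cell
    initiation_flux: float            # alpha, initiations/s per volume (M/s)
    elongating_cores: float           # alpha * tau_c * V, copies per cell
    retained_sigmas: float            # alpha * tau_sigma_eff * V, copies per cell
    tau_sigma: float                  # sigma residence on elongating complex, s
    tau_core: float                   # core residence from initiation to terminator, s


@dataclass(frozen=True)
class CycleState(EquilibriumState):
    """Equilibrium state extended with per-promoter fluxes of the sigma cycle."""

    promoter_states: dict[str, PromoterState] = field(default_factory=dict)
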