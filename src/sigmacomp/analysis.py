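"""Parameter scans, competition onset, response factors and the stringent preset.

Competition onset follows the 5% criterion: the smallest value of the control
parameter (usually the alternative sigma total) at which the housekeeping
holoenzyme level drops to 95% of its reference.  Sensitivity is quantified by
the logarithmic response factor R = d ln(rate) / d ln(x); R > 1 means the
transcriptional output amplifies relative changes of the control parameter
(hypersensitivity), the signature of molecular-titration ultrasensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, minimize_scalar

from .errors import DomainError, SolverError, UsageError
from .scenario import Scenario
from .species import CorePool, PromoterClass, SigmaSpecies
from .units import CellContext

#: Fractional reduction of the reference holoenzyme defining competition onset.
ONSET_THRESHOLD = 0.05


@dataclass(frozen=True)
class ScanResult:
    """Holoenzyme levels and rates along a 1-D scan of one total."""

    control: str
    grid: np.ndarray
    holo: dict[str, np.ndarray]            # total holoenzymes (free + ns-bound)
    free_holo: dict[str, np.ndarray]
    normalized_rate: dict[str, np.ndarray]  # per promoter class
    onset: float | None = None
    response: np.ndarray | None = None
    r_max: float | None = None
    argmax: float | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {self.control: self.grid}
        for name, arr in self.holo.items():
            data[f"holo:{name}"] = arr
        for name, arr in self.free_holo.items():
            data[f"free_holo:{name}"] = arr
        for name, arr in self.normalized_rate.items():
            data[f"rate:{name}"] = arr
        if self.response is not None:
            data["response"] = self.response
        return pd.DataFrame(data)


def scan(scenario: Scenario, control: str, grid: Sequence[float]) -> ScanResult:
    """Solve the configured model at every grid value of the control total."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise UsageError("grid must be a non-empty 1-D array")
    if len(grid) > 1 and not np.all(np.diff(grid) > 0):
        raise UsageError("grid must be strictly increasing")
    scenario.control_value(control)  # validates the name
    holo = {sp.name: np.empty_like(grid) for sp in scenario.species}
    free_holo = {sp.name: np.empty_like(grid) for sp in scenario.species}
    rates = {prm.name: np.empty_like(grid) for prm in scenario.promoters}
    for k, value in enumerate(grid):
        try:
            sc = scenario.with_control(control, value)
            state = sc.solve()
        except SolverError as exc:
            raise SolverError(
                f"scan failed at {control} = {value!r} (grid point {k}): {exc}",
                residual=exc.residual, iterations=exc.iterations) from exc
        for name in holo:
            holo[name][k] = state.pools[name].total_holo
            free_holo[name][k] = state.pools[name].free_holo
        for name, rate in sc.normalized_rates(state).items():
            rates[name][k] = rate
    return ScanResult(control=control, grid=grid, holo=holo,
                      free_holo=free_holo, normalized_rate=rates)


@dataclass(frozen=True)
class OnsetResult:
    """Competition onset: control value of the 5% criterion."""

    value: float | None
    at_reference: bool = False       # criterion already violated at the reference
    reference_level: float | None = None


def _onset_observable(scenario: Scenario, reference_species: str,
                      control: str, value: float) -> float:
    state = scenario.with_control(control, value).solve()
    pools = state.pools[reference_species]
    # Free holoenzymes when NS binding or elongation perturb the pools,
    # total holoenzymes in the bare binding model (where they coincide).
    if scenario.model == "free":
        return pools.total_holo
    return pools.free_holo


def competition_onset(scenario: Scenario, control: str,
                      reference_value: float = 0.0, *,
                      reference_species: str | None = None,
                      start: float | None = None,
                      grid: Sequence[float] | None = None,
                      threshold: float = ONSET_THRESHOLD,
                      rtol: float = 1e-6) -> OnsetResult:
    """Smallest control value at which the reference holoenzyme falls 5% below
    its level at ``reference_value``.

    The criterion level is bracketed on a grid (default 200 log-spaced points
    above the reference) and refined by root bisection to relative ``rtol``.
    Returns ``value=None`` when the reduction is never reached on the grid.
    ``start`` lets the search begin above the reference (an operating point);
    if the criterion is already violated there — the case of housekeeping
    sigma in excess of core, where any competitor bites immediately — the
    onset is reported at ``start`` with ``at_reference`` set.
    """
    if reference_species is None:
        candidates = [sp.name for sp in scenario.species if sp.name != control]
        if not candidates:
            raise UsageError("cannot infer reference_species; pass it explicitly")
        reference_species = candidates[0]

    ref_level = _onset_observable(scenario, reference_species, control,
                                  reference_value)
    if ref_level <= 0:
        raise UsageError(
            f"reference holoenzyme level of {reference_species!r} is 0 at the "
            "reference point; onset is undefined")
    target = (1.0 - threshold) * ref_level

    def deficit(value: float) -> float:
        return _onset_observable(scenario, reference_species, control, value) - target

    start = reference_value if start is None else start
    if deficit(start) <= 0.0:
        return OnsetResult(value=start, at_reference=True,
                           reference_level=ref_level)

    if grid is None:
        lo = max(start, 1.0)
        grid = np.geomspace(lo, lo * 1e5, 200)
    grid = np.asarray(grid, dtype=float)

    prev_x, prev_f = start, deficit(start)
    for x in grid:
        if x <= prev_x:
            continue
        f = deficit(x)
        if f <= 0.0:
            root = brentq(deficit, prev_x, x, rtol=max(rtol, 8.9e-16),
                          xtol=1e-300, maxiter=200)
            return OnsetResult(value=float(root), reference_level=ref_level)
        prev_x, prev_f = x, f
    return OnsetResult(value=None, reference_level=ref_level)


def response_factor(rate: Sequence[float], grid: Sequence[float]) -> np.ndarray:
    """Logarithmic response R = d ln(rate) / d ln(x) by finite differences.

    Central differences in log-log space on the interior, one-sided at the
    endpoints.  Exact for power laws on any positive grid.
    """
    rate = np.asarray(rate, dtype=float)
    x = np.asarray(grid, dtype=float)
    if rate.shape != x.shape or rate.ndim != 1 or len(rate) < 2:
        raise UsageError("rate and grid must be 1-D arrays of equal length >= 2")
    if np.any(rate <= 0):
        raise DomainError("argument 'rate' must be > 0 everywhere for a "
                          "logarithmic response")
    if np.any(x <= 0):
        raise DomainError("argument 'grid' must be > 0 everywhere")
    return np.gradient(np.log(rate), np.log(x), edge_order=2)


def _rate_on_grid(scenario: Scenario, control: str, grid: np.ndarray,
                  promoter: str) -> np.ndarray:
    result = scan(scenario, control, grid)
    if promoter not in result.normalized_rate:
        raise UsageError(f"no promoter class named {promoter!r} in scenario")
    return result.normalized_rate[promoter]


def max_response(scenario: Scenario, control: str, grid: Sequence[float], *,
                 promoter: str | None = None) -> tuple[float, float]:
    """Locate the maximum of the response factor along a scan.

    The normalized rate of the target promoter class (default: the single
    configured class) is scanned over ``grid``; R is interpolated by a cubic
    spline of ln(rate) vs ln(x) and its maximum refined by bounded scalar
    minimization between the bracketing grid points.  Returns
    ``(x_at_max, r_max)``; ``r_max > 1`` signals hypersensitivity.
    """
    grid = np.asarray(grid, dtype=float)
    if promoter is None:
        if len(scenario.promoters) != 1:
            raise UsageError("scenario has several promoter classes; pass promoter=")
        promoter = scenario.promoters[0].name
    rate = _rate_on_grid(scenario, control, grid, promoter)
    if np.any(rate <= 0):
        raise DomainError("normalized rate is 0 on part of the grid; shrink it")
    lx, lr = np.log(grid), np.log(rate)
    spline = CubicSpline(lx, lr)
    dspline = spline.derivative()
    r_grid = dspline(lx)
    k = int(np.argmax(r_grid))
    lo = lx[max(k - 1, 0)]
    hi = lx[min(k + 1, len(lx) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda u: -dspline(u), bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": 1e-12 * max(abs(hi), 1.0)})
        u = float(res.x)
    else:
        u = float(lx[k])
    return math.exp(u), float(dspline(u))


def hypersensitivity_condition(sigma70_total: float, sigma_alt_total: float,
                               kd70: float | None = None,
                               kd_alt: float | None = None) -> bool:
    """Necessary (not sufficient) condition for a response-factor maximum.

    In the strong-binding limit the alternative-sigma response to core
    availability can only peak (R > 1) if the alternative sigma pool is
    strictly smaller than the housekeeping pool.  Equality returns False
    (strict-inequality convention).  The dissociation constants are accepted
    for signature compatibility; for nM-scale binding the exact condition's
    right-hand side is indistinguishable from 1.
    """
    if sigma70_total < 0 or sigma_alt_total < 0:
        raise DomainError("sigma totals must be >= 0")
    return sigma_alt_total < sigma70_total


@dataclass(frozen=True)
class StringentScenario:
    """Bookkeeping of RNA polymerase pools for the stringent-response scenario.

    A rapidly growing E. coli cell (2.5 doublings/h) holds 11400 core RNAPs:
    1100 immature, 2600 transcribing rRNA, 700 transcribing mRNA and 7000
    free or non-specifically DNA-bound.  ppGpp-mediated shutdown of rrn
    transcription releases the rRNA-transcribing cores.
    """

    rnap_total: float = 11400.0
    immature: float = 1100.0
    rrn_transcribing: float = 2600.0
    mrna_transcribing: float = 700.0
    free_or_ns: float = 7000.0
    sigma70_available: float = 9000.0
    sigma_alt: float = 5000.0
    km: float = 1e-5
    kd70: float = 1e-9
    kd_alt: float = 4e-9
    growth_rate_label: str = "2.5 dbl/h"

    def __post_init__(self) -> None:
        pools = (self.immature + self.rrn_transcribing
                 + self.mrna_transcribing + self.free_or_ns)
        if not math.isclose(pools, self.rnap_total, rel_tol=1e-12):
            raise DomainError(
                f"core pools sum to {pools}, not rnap_total = {self.rnap_total}")

    @property
    def available_before(self) -> float:
        """Cores available to transcribe mRNA during exponential growth."""
        return self.free_or_ns + self.mrna_transcribing

    @property
    def available_after(self) -> float:
        """Cores available after rrn shutdown: everything but immature RNAPs."""
        return self.rnap_total - self.immature

    def to_scenario(self, core_total: float | None = None) -> Scenario:
        """Free-binding competition scenario at a given core availability."""
        species = (
            SigmaSpecies(name="sigma70", total=self.sigma70_available,
                         kd_core=self.kd70),
            SigmaSpecies(name="sigmaAlt", total=self.sigma_alt,
                         kd_core=self.kd_alt),
        )
        promoters = (
            PromoterClass(name="PmRNA", cognate_sigma="sigma70", km=self.km),
            PromoterClass(name="PAlt", cognate_sigma="sigmaAlt", km=self.km),
        )
        total = self.available_after if core_total is None else core_total
        return Scenario(species=species, core=CorePool(total=total),
                        promoters=promoters, model="free")


def stringent_preset() -> StringentScenario:
    """The stringent-response parameterization with its derived core pools."""
    return StringentScenario()
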