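"""Estimation of dissociation and Michaelis constants from titration assays.

Three assay designs are supported, mirroring classic in vitro experiments:

* binding titration — fixed core, one sigma species titrated, readout the
  holoenzyme level normalized to its plateau (all cores bound); fits the
  sigma-core dissociation constant through the exact single-species quadratic;
* transcription titration — same design read out as normalized transcription
  rate; joint fit of the sigma-core kd and the promoter Michaelis constant;
* equimolar competition mix — all species titrated together against a fixed
  core pool; fits the vector of dissociation constants *relative* to a
  reference species using the strong-binding partition, for which only kd
  ratios are identifiable (gauge property).

All fits are unweighted nonlinear least squares (scipy ``least_squares``)
with multi-start over a log-spaced kd grid to avoid local minima in the
saturating regime.  Concentrations are molar throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .equilibrium import (holoenzyme_single, solve_partition,
                          strong_binding_partition)
from .errors import DomainError, UsageError, check_nonnegative
from .species import CorePool, SigmaSpecies
from .units import MOLAR_CONTEXT

_KD_START_GRID = np.geomspace(1e-12, 1e-6, 7)
_KD_BOUNDS_LOG10 = (-14.0, -2.0)


@dataclass(frozen=True)
class TitrationDataset:
    """One titration curve: total sigma concentration vs. measured response.

    ``x`` is the varied total sigma concentration (molar; for equimolar mixes
    the common per-species concentration), ``y`` the measured response and
    ``y_kind`` one of ``"holo_fraction"`` (holoenzyme normalized to plateau),
    ``"normalized_rate"`` or ``"bound_fraction"`` (fraction of this species'
    sigma in holoenzymes, the mix readout).
    """

    x: np.ndarray
    y: np.ndarray
    y_kind: str
    core_total: float
    species: str = "sigma"
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or x.shape != y.shape:
            raise DomainError("x and y must be 1-D arrays of equal length")
        if np.any(x <= 0):
            raise DomainError("argument 'x' must be strictly positive")
        if len(x) > 1 and not np.all(np.diff(x) > 0):
            raise DomainError("argument 'x' must be strictly increasing")
        if np.any(y < 0) or np.any(y > 1.0 + 3.0 * self.noise_sd + 1e-12):
            raise DomainError(
                f"argument 'y' must lie in [0, 1 + 3*noise_sd]")
        check_nonnegative(core_total=self.core_total, noise_sd=self.noise_sd)
        if self.y_kind not in ("holo_fraction", "normalized_rate", "bound_fraction"):
            raise DomainError(f"unknown y_kind {self.y_kind!r}")


@dataclass(frozen=True)
class FitResult:
    """Point estimates with asymptotic standard errors and diagnostics."""

    params: dict[str, float]
    stderr: dict[str, float]
    rss: float
    converged: bool
    iterations: int
    flags: tuple[str, ...] = ()


def binding_curve(x: np.ndarray, core_total: float, kd: float) -> np.ndarray:
    """Forward model of the binding titration: h(x) / plateau, plateau = core.

    The plateau is the model's own saturation limit (all cores in
    holoenzymes), not a free parameter.
    """
    h = np.array([holoenzyme_single(core_total, xi, kd) for xi in np.atleast_1d(x)])
    return h / core_total


def transcription_curve(x: np.ndarray, core_total: float, kd: float,
                        km: float) -> np.ndarray:
    """Forward model of the transcription titration, normalized to saturation.

    y = [h/(K_M + h)] / [c/(K_M + c)]  with h from the exact quadratic; the
    denominator is the rate at the sigma -> infinity plateau where h -> core.
    """
    h = np.array([holoenzyme_single(core_total, xi, kd) for xi in np.atleast_1d(x)])
    plateau = core_total / (km + core_total)
    return (h / (km + h)) / plateau


def _asymptotic_se(res, n_obs: int) -> np.ndarray:
    """Heteroscedasticity-robust (sandwich) standard errors at the optimum.

    Titration readouts scale with signal, so the residual variance is not
    constant across the curve; the sandwich estimator
    ``inv(J'J) J' diag(r^2) J inv(J'J)`` stays calibrated there, while the
    classical ``s^2 inv(J'J)`` form understates the error of the estimate.
    """
    n_par = res.x.size
    dof = max(n_obs - n_par, 1)
    try:
        bread = np.linalg.inv(res.jac.T @ res.jac)
    except np.linalg.LinAlgError:
        return np.full(n_par, np.nan)
    meat = res.jac.T @ (res.fun[:, None] ** 2 * res.jac)
    cov = bread @ meat @ bread * (n_obs / dof)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def fit_binding_titration(data: TitrationDataset) -> FitResult:
    """Estimate the sigma-core dissociation constant from a binding titration.

    Least squares over log10(kd) with multi-start on a 1e-12 ... 1e-6 M grid;
    deterministic given the data.  A design with no variation in x, or an
    estimate pinned to the search boundary, is flagged rather than raised.
    """
    if data.y_kind != "holo_fraction":
        raise UsageError(f"expected y_kind 'holo_fraction', got {data.y_kind!r}")
    if len(data.x) < 4:
        raise UsageError("at least 4 titration points are required")
    flags: list[str] = []
    if np.ptp(data.x) == 0.0 or np.ptp(data.y) < 1e-14:
        return FitResult(params={}, stderr={}, rss=float("nan"),
                         converged=False, iterations=0,
                         flags=("non_identifiable",))

    def residuals(p: np.ndarray) -> np.ndarray:
        return binding_curve(data.x, data.core_total, 10.0 ** p[0]) - data.y

    best = None
    for kd0 in _KD_START_GRID:
        res = least_squares(residuals, x0=[math.log10(kd0)],
                            bounds=([_KD_BOUNDS_LOG10[0]], [_KD_BOUNDS_LOG10[1]]),
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or res.cost < best.cost:
            best = res
    kd = 10.0 ** best.x[0]
    se_log = _asymptotic_se(best, len(data.x))[0]
    se_kd = kd * math.log(10.0) * se_log
    if (best.x[0] - _KD_BOUNDS_LOG10[0] < 1e-6
            or _KD_BOUNDS_LOG10[1] - best.x[0] < 1e-6):
        flags.append("boundary")
    return FitResult(params={"kd_core": kd}, stderr={"kd_core": se_kd},
                     rss=float(2.0 * best.cost), converged=bool(best.success),
                     iterations=int(best.nfev), flags=tuple(flags))


def fit_transcription_titration(data: TitrationDataset, *,
                                km_fixed: float | None = None) -> FitResult:
    """Jointly estimate (kd_core, K_M) from a normalized-rate titration.

    With ``km_fixed`` the problem reduces to the one-parameter binding fit on
    the rate scale.  When the two constants are nearly exchangeable on the
    given design (parameter correlation > 0.999) the result carries an
    ``"exchangeable"`` identifiability flag.
    """
    if data.y_kind != "normalized_rate":
        raise UsageError(f"expected y_kind 'normalized_rate', got {data.y_kind!r}")
    if len(data.x) < 4:
        raise UsageError("at least 4 titration points are required")
    if np.ptp(data.x) == 0.0 or np.ptp(data.y) < 1e-14:
        return FitResult(params={}, stderr={}, rss=float("nan"),
                         converged=False, iterations=0,
                         flags=("non_identifiable",))
    flags: list[str] = []

    if km_fixed is not None:
        def residuals(p):
            return (transcription_curve(data.x, data.core_total,
                                        10.0 ** p[0], km_fixed) - data.y)
        best = None
        for kd0 in _KD_START_GRID:
            res = least_squares(residuals, x0=[math.log10(kd0)],
                                bounds=([_KD_BOUNDS_LOG10[0]], [_KD_BOUNDS_LOG10[1]]),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
            if best is None or res.cost < best.cost:
                best = res
        kd = 10.0 ** best.x[0]
        se = _asymptotic_se(best, len(data.x))
        return FitResult(params={"kd_core": kd, "km": km_fixed},
                         stderr={"kd_core": kd * math.log(10.0) * se[0], "km": 0.0},
                         rss=float(2.0 * best.cost), converged=bool(best.success),
                         iterations=int(best.nfev), flags=tuple(flags))

    def residuals(p):
        return (transcription_curve(data.x, data.core_total,
                                    10.0 ** p[0], 10.0 ** p[1]) - data.y)

    starts = [(kd0, km0) for kd0 in np.geomspace(1e-11, 1e-6, 4)
              for km0 in np.geomspace(1e-10, 1e-5, 4)]
    best = None
    for kd0, km0 in starts:
        res = least_squares(residuals, x0=[math.log10(kd0), math.log10(km0)],
                            bounds=([_KD_BOUNDS_LOG10[0]] * 2,
                                    [_KD_BOUNDS_LOG10[1]] * 2),
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or res.cost < best.cost:
            best = res
    kd, km = 10.0 ** best.x[0], 10.0 ** best.x[1]
    se = _asymptotic_se(best, len(data.x))
    jtj = best.jac.T @ best.jac
    if jtj.shape == (2, 2) and jtj[0, 0] > 0 and jtj[1, 1] > 0:
        corr = abs(jtj[0, 1]) / math.sqrt(jtj[0, 0] * jtj[1, 1])
        if corr > 0.999:
            flags.append("exchangeable")
    return FitResult(
        params={"kd_core": kd, "km": km},
        stderr={"kd_core": kd * math.log(10.0) * se[0],
                "km": km * math.log(10.0) * se[1]},
        rss=float(2.0 * best.cost), converged=bool(best.success),
        iterations=int(best.nfev), flags=tuple(flags))


def mix_fractions(x: float, rel_kds: Sequence[float],
                  core_total: float) -> np.ndarray:
    """Bound fraction of each species in an equimolar mix, strong-binding limit."""
    holo = strong_binding_partition([x] * len(rel_kds), core_total, rel_kds)
    return holo / x


def fit_relative_kds(mix_data: Sequence[TitrationDataset], *,
                     reference: str | None = None) -> FitResult:
    """Relative dissociation constants from an equimolar competition mix.

    All datasets share the same equimolar concentration grid and core pool.
    The forward model is the strong-binding partition, which depends on kd
    ratios only; the reference species' relative kd is fixed at 1 and the
    remaining log-ratios are fitted to all species' bound-fraction curves
    simultaneously.
    """
    if len(mix_data) < 2:
        raise UsageError("at least 2 species are required for a relative-kd fit")
    names = [d.species for d in mix_data]
    if len(set(names)) != len(names):
        raise UsageError(f"duplicate species labels in mix data: {names}")
    x = mix_data[0].x
    core_total = mix_data[0].core_total
    for d in mix_data[1:]:
        if not np.array_equal(d.x, x) or d.core_total != core_total:
            raise UsageError("all mix datasets must share x grid and core_total")
        if d.y_kind != "bound_fraction":
            raise UsageError(f"expected y_kind 'bound_fraction', got {d.y_kind!r}")
    if mix_data[0].y_kind != "bound_fraction":
        raise UsageError("expected y_kind 'bound_fraction'")
    reference = reference or names[0]
    if reference not in names:
        raise UsageError(f"reference {reference!r} not among species {names}")
    free_idx = [i for i, n in enumerate(names) if n != reference]
    ref_idx = names.index(reference)
    y_obs = np.stack([d.y for d in mix_data])

    def rel_vector(p: np.ndarray) -> np.ndarray:
        r = np.empty(len(names))
        r[ref_idx] = 1.0
        for k, i in enumerate(free_idx):
            r[i] = 10.0 ** p[k]
        return r

    def residuals(p: np.ndarray) -> np.ndarray:
        r = rel_vector(p)
        pred = np.stack([mix_fractions(xi, r, core_total) for xi in x], axis=1)
        return (pred - y_obs).ravel()

    # Heuristic start: species bound less than the reference bind more weakly.
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.nanmean(
            np.where(y_obs > 1e-9, y_obs[ref_idx] / np.maximum(y_obs, 1e-9), np.nan),
            axis=1)
    heuristic = np.log10(np.clip(ratio[free_idx], 1e-3, 1e3))
    best = None
    for x0 in (np.zeros(len(free_idx)), heuristic):
        res = least_squares(residuals, x0=x0, bounds=(-6.0, 6.0),
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or res.cost < best.cost:
            best = res
    se = _asymptotic_se(best, y_obs.size)
    r = rel_vector(best.x)
    params = {f"rel_kd:{n}": float(r[i]) for i, n in enumerate(names)}
    stderr = {f"rel_kd:{reference}": 0.0}
    for k, i in enumerate(free_idx):
        stderr[f"rel_kd:{names[i]}"] = float(r[i] * math.log(10.0) * se[k])
    return FitResult(params=params, stderr=stderr, rss=float(2.0 * best.cost),
                     converged=bool(best.success), iterations=int(best.nfev))


def competition_prediction(kds: dict[str, float], equimolar_grid: Sequence[float],
                           core_total: float) -> dict[str, np.ndarray]:
    """Predict mix bound fractions from singly-fitted absolute kds (no refit).

    Forward N-species equilibrium solve at each equimolar concentration;
    returns per-species arrays of the fraction of that sigma bound in
    holoenzymes.  This is the validation logic of fitting each sigma alone
    and predicting the competition mix.
    """
    grid = np.asarray(equimolar_grid, dtype=float)
    core = CorePool(total=core_total)
    out = {n: np.empty_like(grid) for n in kds}
    for k, x in enumerate(grid):
        species = [SigmaSpecies(name=n, total=x, kd_core=kd)
                   for n, kd in kds.items()]
        state = solve_partition(species, core, MOLAR_CONTEXT)
        for n in kds:
            out[n][k] = state.pools[n].free_holo / x
    return out
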