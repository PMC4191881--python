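"""Binding equilibrium of sigma factors competing for core RNA polymerase.

The central problem: N sigma species with totals sigma_i and dissociation
constants K_i compete for a shared pool of core enzyme E_c.  At equilibrium

    K_i = [E_free][sigma_i,free] / [E sigma_i]

together with one conservation law per species and one for core.  Optional
layers handled in the same scalar root-find: anti-sigma sequestration
(closed-form quadratic per species at fixed free core) and non-specific DNA
binding of cores and holoenzymes under the excess-sites approximation.

All functions here work in molar; counts enter and leave through
:class:`~sigmacomp.units.CellContext`.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import (DomainError, SolverError, UsageError,
                     check_nonnegative, check_positive)
from .species import (CorePool, EquilibriumState, NonSpecificParams,
                      SigmaSpecies, SpeciesPools)
from .units import CellContext

_BRENTQ_KW = dict(xtol=1e-300, rtol=8.9e-16, maxiter=200)


def holoenzyme_single(core_total: float, sigma_total: float, kd: float) -> float:
    """Holoenzyme concentration for one sigma species, exact quadratic root.

    Solves ``(c - h)(s - h) = K h`` for the physical root
    ``0 <= h <= min(c, s)`` using the cancellation-free form
    ``h = 2 c s / (b + sqrt(b^2 - 4 c s))`` with ``b = c + s + K``,
    which stays accurate for ``K`` many orders of magnitude below the totals.

    Parameters are molar; the result is molar.
    """
    check_nonnegative(core_total=core_total, sigma_total=sigma_total)
    check_positive(kd=kd)
    if core_total == 0.0 or sigma_total == 0.0:
        return 0.0
    b = core_total + sigma_total + kd
    disc = b * b - 4.0 * core_total * sigma_total
    return 2.0 * core_total * sigma_total / (b + math.sqrt(disc))


def holoenzyme_strong_limit(core_total: float, sigma_total: float) -> float:
    """Strong-binding (kd -> 0) limit: the smaller of the two totals."""
    check_nonnegative(core_total=core_total, sigma_total=sigma_total)
    return min(core_total, sigma_total)


def holoenzyme_ratio(kd_i: float, kd_j: float,
                     free_sigma_i: float, free_sigma_j: float) -> float:
    """Ratio law: holo_i / holo_j = (K_j / K_i) * (sigma_i,free / sigma_j,free).

    The ratio of two holoenzyme concentrations depends only on the species'
    relative dissociation constants and free sigma concentrations, regardless
    of how many other species compete.  Used as an internal consistency check
    and as the basis of pairwise relative-kd estimation.
    """
    check_positive(kd_i=kd_i, kd_j=kd_j)
    check_nonnegative(free_sigma_i=free_sigma_i, free_sigma_j=free_sigma_j)
    if free_sigma_j == 0.0:
        raise DomainError("holoenzyme_ratio undefined: free_sigma_j is 0")
    return (kd_j / kd_i) * (free_sigma_i / free_sigma_j)


def anti_sigma_partition(sigma_total: float, anti_total: float, kd_anti: float,
                         free_core: float, kd_core: float,
                         holo_factor: float = 1.0) -> tuple[float, float, float]:
    """Partition one sigma species among free, holoenzyme and anti-sigma pools.

    Free core is held at a fixed concentration (it is the outer root-find
    variable); the anti-sigma factor has its own conservation law, giving a
    closed-form quadratic in free anti-sigma.  ``holo_factor`` multiplies the
    holoenzyme pool per unit free holoenzyme (``1 + D/K_NS`` when holoenzymes
    also bind DNA non-specifically; 1 otherwise).

    Returns ``(free_sigma, free_anti, complex)`` in molar, where ``complex``
    is the sigma:anti-sigma complex concentration.
    """
    check_nonnegative(sigma_total=sigma_total, anti_total=anti_total,
                      free_core=free_core)
    check_positive(kd_anti=kd_anti, kd_core=kd_core, holo_factor=holo_factor)
    # beta = sigma_total / free_sigma in the absence of anti-sigma
    beta = 1.0 + (free_core / kd_core) * holo_factor
    if anti_total == 0.0:
        return sigma_total / beta, 0.0, 0.0
    # Conservation of anti: A_free^2 + A_free (K beta + s - A) - A K beta = 0
    kb = kd_anti * beta
    b = kb + sigma_total - anti_total
    disc = b * b + 4.0 * anti_total * kb
    sqrt_disc = math.sqrt(disc)
    if b >= 0.0:
        free_anti = 2.0 * anti_total * kb / (b + sqrt_disc)
    else:
        free_anti = (-b + sqrt_disc) / 2.0
    free_sigma = sigma_total / (beta + free_anti / kd_anti)
    complex_ = free_sigma * free_anti / kd_anti
    return free_sigma, free_anti, complex_


def strong_binding_partition(sigma_totals: Sequence[float], core_total: float,
                             rel_kds: Sequence[float]) -> np.ndarray:
    """Holoenzyme partition in the strong-binding limit (all kd -> 0 at fixed ratios).

    When core is in excess of total sigma every sigma is in a holoenzyme.
    Otherwise all cores are bound and the partition solves

        sum_i sigma_i * y / (r_i + y) = E_c,tot

    for the scaled free-core variable ``y``; species with smaller relative
    dissociation constant ``r_i`` claim proportionally more core.  With equal
    ``r_i`` this reduces to proportional allocation ``h_i = E_c sigma_i / sum sigma``.
    """
    sig = np.asarray(sigma_totals, dtype=float)
    r = np.asarray(rel_kds, dtype=float)
    if sig.shape != r.shape:
        raise UsageError("sigma_totals and rel_kds must have the same length")
    if np.any(sig < 0) or core_total < 0:
        raise DomainError("totals must be >= 0")
    if np.any(r <= 0):
        raise DomainError("relative dissociation constants must be > 0")
    total_sigma = sig.sum()
    if total_sigma <= core_total or total_sigma == 0.0:
        return sig.copy()

    def deficit(y: float) -> float:
        return float(np.sum(sig * y / (r + y))) - core_total

    if core_total == 0.0:
        return np.zeros_like(sig)
    # Bracket: deficit(0) = -core < 0; deficit(y) -> total_sigma - core > 0.
    hi = r.max()
    while deficit(hi) < 0.0:
        hi *= 10.0
    y = brentq(deficit, 0.0, hi, **_BRENTQ_KW)
    return sig * y / (r + y)


def _species_partition(sigma_avail: float, kd: float, anti_total: float,
                       kd_anti: float | None, x: float, holo_factor: float):
    """Free sigma, free anti, anti complex and free holoenzyme at free core x."""
    if anti_total > 0:
        free_sigma, free_anti, complex_ = anti_sigma_partition(
            sigma_avail, anti_total, kd_anti, x, kd, holo_factor)
    else:
        beta = 1.0 + (x / kd) * holo_factor
        free_sigma, free_anti, complex_ = sigma_avail / beta, 0.0, 0.0
    free_holo = free_sigma * x / kd
    return free_sigma, free_anti, complex_, free_holo


def solve_partition(species: Sequence[SigmaSpecies], core: CorePool,
                    context: CellContext, *,
                    ns: NonSpecificParams | None = None,
                    kd_override: dict[str, float] | None = None,
                    sigma_available: dict[str, float] | None = None,
                    core_available: float | None = None,
                    extra_pools: dict[str, SpeciesPools] | None = None,
                    iterations: int = 1) -> EquilibriumState:
    """Workhorse: bracketed scalar root-find on free core concentration.

    ``sigma_available``/``core_available`` (counts) let the transcription
    cycle remove sequestered molecules from the binding competition;
    ``kd_override`` substitutes effective dissociation constants;
    ``extra_pools`` merges promoter/elongation pools into the reported state.
    The conservation residual is strictly monotone in free core, so the root
    in ``[0, E_c,avail]`` is unique.
    """
    if len(species) == 0:
        raise UsageError("at least one sigma species is required")
    names = [sp.name for sp in species]
    if len(set(names)) != len(names):
        raise UsageError(f"duplicate species names in {names}")

    d_conc = context.ns_sites_molar if ns is not None else 0.0
    f_core = 1.0 + (d_conc / ns.kd_ns_core if ns is not None else 0.0)
    f_holo = {sp.name: 1.0 + (d_conc / ns.holo_kd(sp) if ns is not None else 0.0)
              for sp in species}

    kds = {sp.name: (kd_override or {}).get(sp.name, sp.kd_core) for sp in species}
    for name, kd in kds.items():
        if not kd > 0:
            raise DomainError(f"dissociation constant for {name!r} must be > 0, got {kd!r}")

    core_total_counts = core.total if core_available is None else core_available
    core_total = context.counts_to_molar(max(core_total_counts, 0.0))
    sig_avail = {}
    for sp in species:
        counts = sp.total if sigma_available is None else sigma_available[sp.name]
        sig_avail[sp.name] = context.counts_to_molar(max(counts, 0.0))

    anti_molar = {sp.name: context.counts_to_molar(sp.anti_total) for sp in species}

    def partition_at(x: float):
        out = {}
        for sp in species:
            out[sp.name] = _species_partition(
                sig_avail[sp.name], kds[sp.name], anti_molar[sp.name],
                sp.kd_anti, x, f_holo[sp.name])
        return out

    def core_balance(x: float) -> float:
        parts = partition_at(x)
        bound = sum(parts[sp.name][3] * f_holo[sp.name] for sp in species)
        return x * f_core + bound - core_total

    if core_total == 0.0 or all(v == 0.0 for v in sig_avail.values()):
        x = core_total / f_core
    else:
        x = brentq(core_balance, 0.0, core_total, **_BRENTQ_KW)

    parts = partition_at(x)
    pools: dict[str, SpeciesPools] = {}
    residuals: dict[str, float] = {}
    for sp in species:
        free_sigma, free_anti, complex_, free_holo = parts[sp.name]
        extra = (extra_pools or {}).get(sp.name)
        p = SpeciesPools(
            free_sigma=context.molar_to_counts(free_sigma),
            free_holo=context.molar_to_counts(free_holo),
            ns_bound_holo=context.molar_to_counts(free_holo * (f_holo[sp.name] - 1.0)),
            anti_bound_sigma=context.molar_to_counts(complex_),
            promoter_bound_holo=extra.promoter_bound_holo if extra else 0.0,
            elongating_cores=extra.elongating_cores if extra else 0.0,
            retained_sigmas=extra.retained_sigmas if extra else 0.0,
        )
        pools[sp.name] = p
        scale = max(sp.total, 1.0)
        residuals[sp.name] = abs(p.sigma_sum - sp.total) / scale

    free_core_counts = context.molar_to_counts(x)
    ns_core_counts = context.molar_to_counts(x * (f_core - 1.0))
    core_sum = (free_core_counts + ns_core_counts
                + sum(p.core_sum for p in pools.values()))
    residuals["core"] = abs(core_sum - core.total) / max(core.total, 1.0)

    return EquilibriumState(
        species_names=tuple(names),
        pools=pools,
        free_core=free_core_counts,
        ns_bound_core=ns_core_counts,
        effective_kd=dict(kds),
        context=context,
        residuals=residuals,
        iterations=iterations,
        converged=True,
    )


def solve_free_binding(species: Sequence[SigmaSpecies], core: CorePool,
                       context: CellContext | None = None) -> EquilibriumState:
    """Partition core RNAP among N sigma species in the absence of DNA.

    Anti-sigma sequestration (per-species closed-form quadratic) is resolved
    inside the scalar root-find on free core.  Deterministic; raises
    :class:`UsageError` on an empty species list.
    """
    context = context or CellContext()
    return solve_partition(species, core, context)


def ns_scaling_factor(ns_sites_conc: float, kd_ns: float) -> float:
    """Probability that a molecule is cytoplasmically free: 1 / (1 + D / K_NS).

    Excess-sites approximation: free non-specific sites ~ total sites D.
    """
    check_nonnegative(ns_sites_conc=ns_sites_conc)
    check_positive(kd_ns=kd_ns)
    return 1.0 / (1.0 + ns_sites_conc / kd_ns)


def solve_with_ns(species: Sequence[SigmaSpecies], core: CorePool,
                  ns: NonSpecificParams, context: CellContext | None = None
                  ) -> EquilibriumState:
    """Equilibrium with non-specific DNA binding of cores and holoenzymes.

    Under the excess-sites approximation every free core/holoenzyme pool is
    mirrored by an ns-bound pool ``D/K_NS`` times larger.  When all K_NS are
    equal, total holoenzymes match the no-DNA solution and free pools are the
    totals rescaled by :func:`ns_scaling_factor` (the rescaling property);
    unequal constants break this and shift the competition.
    """
    context = context or CellContext()
    if context.ns_sites == 0:
        return solve_partition(species, core, context)
    return solve_partition(species, core, context, ns=ns)
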