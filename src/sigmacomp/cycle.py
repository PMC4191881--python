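"""Self-consistent steady state of the full sigma cycle.

Transcription feeds back on the binding competition in two ways:

* sequestration — promoter-bound holoenzymes, elongating cores (committed for
  the operon length) and retained sigmas (committed for the retention length)
  are unavailable for binding;
* effective affinity — initiation actively separates sigma from core after
  the retention length, adding a dissociation pathway on top of spontaneous
  unbinding.  The apparent dissociation constant becomes

      K_eff = K + alpha / (k_on * h_free)

  where alpha is the initiation flux per volume.  If core and sigma leave the
  cycle together as a holoenzyme, no extra separation occurs and K_eff = K.

The steady state is found by damped fixed-point iteration alternating the
inner binding equilibrium (with sequestered pools removed and K_eff
substituted) and the recomputation of fluxes and sequestration.
"""

from __future__ import annotations

from typing import Sequence

from .errors import (ConfigError, InconsistentStateError, SolverError,
                     check_nonnegative, check_positive)
from .species import (CorePool, CycleState, EquilibriumState,
                      NonSpecificParams, PromoterClass, PromoterState,
                      SigmaSpecies, SpeciesPools)
from .transcription import promoter_conc
from .units import CellContext
from .equilibrium import holoenzyme_single, solve_partition


def retention_times(promoter: PromoterClass) -> tuple[float, float]:
    """Residence times (seconds) of sigma and core on the elongating complex.

    tau_sigma = retention_length / v, tau_core = operon_length / v.  For the
    default 300 nt retention at 55 nt/s sigma stays about 5 s, while a
    1500-6000 nt operon commits the core for 30-120 s.
    """
    return (promoter.retention_length / promoter.elongation_speed,
            promoter.operon_length / promoter.elongation_speed)


def effective_kd(kd: float, kon: float, alpha_per_volume: float,
                 holo_free: float) -> float:
    """Effective sigma-core dissociation constant under active transcription.

    ``alpha_per_volume / holo_free`` is the per-holoenzyme separation rate
    added to the spontaneous off-rate ``kon * kd``; hence
    ``K_eff = K + alpha / (kon * h)``.  Recovers K as the flux vanishes or as
    binding (kon) dominates.
    """
    check_positive(kd=kd, kon=kon)
    check_nonnegative(alpha_per_volume=alpha_per_volume, holo_free=holo_free)
    if alpha_per_volume == 0.0:
        return kd
    if holo_free == 0.0:
        raise InconsistentStateError(
            "transcription flux > 0 with zero free holoenzyme")
    return kd + alpha_per_volume / (kon * holo_free)


def _promoter_update(promoters: Sequence[PromoterClass],
                     state: EquilibriumState, context: CellContext,
                     bound_prev: dict[str, float]):
    """Fluxes, occupancies and sequestered pools from current free holoenzymes.

    Promoter-bound complexes are computed from finite-pool mass action: the
    holoenzymes available to a promoter class (free plus currently bound)
    partition onto the promoter sites via the exact quadratic with an
    effective Michaelis constant K_M * (1 + sum_r r/K_rep) carrying repressor
    competition.  At the fixed point this is identical to the Michaelis
    occupancy h/(K_M' + h) per promoter, but it can never bind more
    holoenzymes than exist, which keeps the outer iteration stable when a
    sigma species is scarce.
    """
    holo_molar = {name: state.free_holo_molar(name) for name in state.species_names}
    promoter_states: dict[str, PromoterState] = {}
    seq_sigma = {name: 0.0 for name in state.species_names}
    seq_holo_on_promoter = {name: 0.0 for name in state.species_names}
    elongating = {name: 0.0 for name in state.species_names}
    alpha_separate = {name: 0.0 for name in state.species_names}
    for prm in promoters:
        h = holo_molar[prm.cognate_sigma]
        rep_load = sum(holo_molar[label] / kd_rep
                       for label, kd_rep in prm.repressors)
        km_eff = prm.km * (1.0 + rep_load)
        pool = h + context.counts_to_molar(bound_prev.get(prm.name, 0.0))
        p_conc = promoter_conc(prm, context)
        if p_conc > 0.0 and pool > 0.0:
            bound_molar = holoenzyme_single(pool, p_conc, km_eff)
        else:
            bound_molar = 0.0
        bound = context.molar_to_counts(bound_molar)
        theta = bound / prm.count if prm.count > 0 else 0.0
        alpha = prm.kmax * bound_molar  # initiations per second per volume
        tau_sigma, tau_core = retention_times(prm)
        if prm.release_mode == "holoenzyme_release":
            tau_sigma_eff = tau_core   # sigma rides with core to the terminator
        else:
            tau_sigma_eff = tau_sigma
            alpha_separate[prm.cognate_sigma] += alpha
        elong = context.molar_to_counts(alpha * tau_core)
        retained = context.molar_to_counts(alpha * tau_sigma_eff)
        promoter_states[prm.name] = PromoterState(
            name=prm.name, occupancy=theta, bound_holo=bound,
            initiation_flux=alpha, elongating_cores=elong,
            retained_sigmas=retained, tau_sigma=tau_sigma_eff, tau_core=tau_core)
        seq_holo_on_promoter[prm.cognate_sigma] += bound
        elongating[prm.cognate_sigma] += elong
        seq_sigma[prm.cognate_sigma] += retained
    return (promoter_states, seq_sigma, seq_holo_on_promoter, elongating,
            alpha_separate, holo_molar)


def solve_cycle(species: Sequence[SigmaSpecies], core: CorePool,
                promoters: Sequence[PromoterClass],
                ns: NonSpecificParams | None = None,
                context: CellContext | None = None, *,
                damping: float = 0.5, tol: float = 1e-9,
                max_iter: int = 10_000, adaptive_damping: bool = True) -> CycleState:
    """Steady state of binding + promoter occupancy + transcript elongation.

    Damped fixed-point iteration (damping factor ``damping`` on the
    sequestered pools and effective kds) until every pool changes by less
    than ``tol`` relative.  With no promoters this reduces exactly to
    :func:`~sigmacomp.equilibrium.solve_free_binding` /
    :func:`~sigmacomp.equilibrium.solve_with_ns`.

    When the iteration oscillates (it can, when a sigma species is scarce
    relative to its promoters and the K_eff feedback is strong), the damping
    factor is halved every 500 unconverged iterations (``adaptive_damping``);
    a final failure still suggests an explicit smaller factor.
    """
    context = context or CellContext()
    names = {sp.name for sp in species}
    for prm in promoters:
        if prm.cognate_sigma not in names:
            raise ConfigError(
                f"promoter {prm.name!r}: cognate sigma {prm.cognate_sigma!r} "
                f"is not among species {sorted(names)}")
        if prm.release_mode == "separate_release" and prm.kmax > 0:
            sp = next(s for s in species if s.name == prm.cognate_sigma)
            if sp.kon_core is None:
                raise ConfigError(
                    f"species {sp.name!r} needs kon_core for separate_release "
                    f"promoter {prm.name!r}")

    use_ns = ns is not None and context.ns_sites > 0
    ns_arg = ns if use_ns else None

    # Iterated variables: per-species sequestered sigma / core pools and K_eff.
    seq_sigma = {sp.name: 0.0 for sp in species}         # retained during elongation
    seq_promoter = {sp.name: 0.0 for sp in species}      # holoenzymes on promoters
    elongating = {sp.name: 0.0 for sp in species}
    kd_eff = {sp.name: sp.kd_core for sp in species}
    bound_class = {prm.name: 0.0 for prm in promoters}   # per-class promoter-bound

    state = None
    prev = None
    last_delta = float("inf")
    for it in range(1, max_iter + 1):
        sigma_avail = {sp.name: sp.total - seq_promoter[sp.name] - seq_sigma[sp.name]
                       for sp in species}
        core_avail = (core.total - sum(seq_promoter.values())
                      - sum(elongating.values()))
        state = solve_partition(
            species, core, context, ns=ns_arg, kd_override=kd_eff,
            sigma_available=sigma_avail, core_available=core_avail,
            iterations=it)

        (promoter_states, new_seq_sigma, new_seq_promoter, new_elong,
         alpha_separate, holo_molar) = _promoter_update(promoters, state,
                                                        context, bound_class)

        new_kd = {}
        for sp in species:
            alpha = alpha_separate[sp.name]
            # h = 0 with alpha > 0 only occurs transiently while the damped
            # pools settle; the bare kd is the correct zero-flux limit there.
            if alpha == 0.0 or holo_molar[sp.name] == 0.0:
                new_kd[sp.name] = sp.kd_core
            else:
                new_kd[sp.name] = effective_kd(
                    sp.kd_core, sp.kon_core, alpha, holo_molar[sp.name])

        def mix(old: dict, new: dict) -> dict:
            return {k: (1.0 - damping) * old[k] + damping * new[k] for k in old}

        new_bound_class = {name: ps.bound_holo
                           for name, ps in promoter_states.items()}

        current = [v for d in (new_seq_sigma, new_seq_promoter, new_elong, new_kd)
                   for v in d.values()]
        current += [state.pools[n].free_holo for n in state.species_names]
        current.append(state.free_core)
        if prev is not None:
            last_delta = max(abs(a - b) / max(abs(a), abs(b), 1e-30)
                             for a, b in zip(current, prev))
            if last_delta < tol:
                return _assemble(state, species, core, context, promoter_states,
                                 new_seq_sigma, new_seq_promoter, new_elong,
                                 new_kd, it)
        if adaptive_damping and it % 500 == 0 and last_delta > 100.0 * tol:
            damping *= 0.5
        prev = current
        seq_sigma = mix(seq_sigma, new_seq_sigma)
        seq_promoter = mix(seq_promoter, new_seq_promoter)
        elongating = mix(elongating, new_elong)
        kd_eff = mix(kd_eff, new_kd)
        bound_class = mix(bound_class, new_bound_class)

    raise SolverError(
        f"sigma-cycle fixed point did not converge in {max_iter} iterations "
        f"(last relative change {last_delta:.3e}); if the iteration oscillates, "
        f"retry with a smaller damping factor (current {damping})",
        residual=last_delta, iterations=max_iter)


def _assemble(state: EquilibriumState, species, core: CorePool,
              context: CellContext, promoter_states, seq_sigma, seq_promoter,
              elongating, kd_eff, iterations: int) -> CycleState:
    pools = {}
    residuals = {}
    for sp in species:
        p = state.pools[sp.name]
        pools[sp.name] = SpeciesPools(
            free_sigma=p.free_sigma, free_holo=p.free_holo,
            ns_bound_holo=p.ns_bound_holo,
            anti_bound_sigma=p.anti_bound_sigma,
            promoter_bound_holo=seq_promoter[sp.name],
            elongating_cores=elongating[sp.name],
            retained_sigmas=seq_sigma[sp.name])
        residuals[sp.name] = (abs(pools[sp.name].sigma_sum - sp.total)
                              / max(sp.total, 1.0))
    core_sum = (state.free_core + state.ns_bound_core
                + sum(p.core_sum for p in pools.values()))
    residuals["core"] = abs(core_sum - core.total) / max(core.total, 1.0)
    return CycleState(
        species_names=state.species_names, pools=pools,
        free_core=state.free_core, ns_bound_core=state.ns_bound_core,
        effective_kd=dict(kd_eff), context=context, residuals=residuals,
        iterations=iterations, converged=True,
        promoter_states=promoter_states)
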