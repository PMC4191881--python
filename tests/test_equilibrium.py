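"""Core binding-equilibrium solver: closed forms, invariants, ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sigmacomp as sc
from _oracles import free_binding_ode


class TestHoloenzymeSingle:
    # Frozen from a high-precision (30-digit symbolic) evaluation of the
    # quadratic root for 11400 cores and 5700 sigmas in a 1.32 fL cell.
    @pytest.mark.parametrize("kd, expected_counts", [
        (1e-9, 5699.20529904693),
        (1e-6, 5064.54182937902),
    ])
    def test_quadratic_root_frozen_values(self, ctx, kd, expected_counts):
        h = sc.holoenzyme_single(ctx.counts_to_molar(11400),
                                 ctx.counts_to_molar(5700), kd)
        assert ctx.molar_to_counts(h) == pytest.approx(expected_counts, rel=1e-10)

    def test_mass_action_relation_holds(self):
        c, s, kd = 2e-6, 1.3e-6, 3e-9
        h = sc.holoenzyme_single(c, s, kd)
        assert (c - h) * (s - h) == pytest.approx(kd * h, rel=1e-12)

    def test_zero_core_or_sigma_gives_zero(self):
        assert sc.holoenzyme_single(0.0, 1e-6, 1e-9) == 0.0
        assert sc.holoenzyme_single(1e-6, 0.0, 1e-9) == 0.0

    @pytest.mark.parametrize("bad", [
        dict(core_total=-1e-9, sigma_total=1e-9, kd=1e-9),
        dict(core_total=1e-9, sigma_total=-1e-9, kd=1e-9),
        dict(core_total=1e-9, sigma_total=1e-9, kd=0.0),
    ])
    def test_domain_errors_name_argument(self, bad):
        with pytest.raises(sc.DomainError) as err:
            sc.holoenzyme_single(**bad)
        offending = next(k for k, v in bad.items() if v <= 0)
        assert offending in str(err.value)

    @given(c=st.floats(min_value=1e-9, max_value=1e-4),
           s=st.floats(min_value=1e-9, max_value=1e-4),
           log_ratio=st.floats(min_value=4.5, max_value=12.0))
    def test_strong_binding_limit_agreement(self, c, s, log_ratio):
        """kd far below the totals: exact root approaches min(c, s).

        Near-equal totals are excluded: there the limiting error decays only
        as sqrt(kd * c), which is the boundary of the approximation's validity.
        """
        from hypothesis import assume
        assume(abs(c - s) > 0.1 * min(c, s))
        kd = min(c, s) * 10.0 ** (-log_ratio)
        h = sc.holoenzyme_single(c, s, kd)
        limit = sc.holoenzyme_strong_limit(c, s)
        assert abs(h - limit) / min(c, s) < 1e-3

    def test_no_cancellation_for_tiny_kd(self):
        # kd 12 orders below the totals still satisfies mass action
        c, s, kd = 1e-5, 7e-6, 1e-17
        h = sc.holoenzyme_single(c, s, kd)
        assert 0 <= h <= min(c, s)
        assert (c - h) * (s - h) == pytest.approx(kd * h, rel=1e-6)


def test_strong_limit_picks_smaller_total():
    assert sc.holoenzyme_strong_limit(11400, 7600) == 7600
    assert sc.holoenzyme_strong_limit(5, 5) == 5


class TestHoloenzymeRatio:
    def test_equal_everything_is_one(self):
        assert sc.holoenzyme_ratio(1e-9, 1e-9, 1e-7, 1e-7) == 1.0

    def test_twofold_affinity_doubles_ratio(self):
        assert sc.holoenzyme_ratio(0.5e-9, 1e-9, 1e-7, 1e-7) == pytest.approx(2.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(sc.DomainError):
            sc.holoenzyme_ratio(1e-9, 1e-9, 1e-7, 0.0)

    def test_consistent_with_solver_output(self, ctx):
        species = (sc.SigmaSpecies("a", 6000.0, kd_core=2e-9),
                   sc.SigmaSpecies("b", 9000.0, kd_core=7e-9),
                   sc.SigmaSpecies("c", 2500.0, kd_core=0.4e-9))
        state = sc.solve_free_binding(species, sc.CorePool(11400.0), ctx)
        for i, j in [("a", "b"), ("a", "c"), ("b", "c")]:
            pi, pj = state.pools[i], state.pools[j]
            ratio = sc.holoenzyme_ratio(
                state.effective_kd[i], state.effective_kd[j],
                pi.free_sigma, pj.free_sigma)
            assert pi.free_holo / pj.free_holo == pytest.approx(ratio, rel=1e-7)


class TestAntiSigmaPartition:
    def test_no_anti_sigma_reduces_to_core_binding(self):
        s, x, kd = 5e-6, 1e-6, 1e-9
        free_sigma, free_anti, complex_ = sc.anti_sigma_partition(
            s, 0.0, 1e-11, x, kd)
        assert free_anti == 0.0 and complex_ == 0.0
        assert free_sigma == pytest.approx(s / (1 + x / kd), rel=1e-12)

    def test_excess_tight_anti_suppresses_holoenzyme(self, ctx):
        species = (sc.SigmaSpecies("alt", 5000.0, kd_core=1e-9,
                                   anti_total=19000.0, kd_anti=1e-11),)
        state = sc.solve_free_binding(species, sc.CorePool(11400.0), ctx)
        assert state.pools["alt"].free_holo < 0.01 * 5000.0
        assert state.pools["alt"].anti_bound_sigma == pytest.approx(
            5000.0, rel=1e-2)

    def test_matches_independent_quadratic_root(self, ctx):
        # Equimolar sigma and anti-sigma at the tight 0.01 nM affinity, no core
        s = a = ctx.counts_to_molar(5000.0)
        kd_anti = 1e-11
        free_sigma, free_anti, complex_ = sc.anti_sigma_partition(
            s, a, kd_anti, 0.0, 1e-9)
        # independent root: numpy polynomial solve of the conservation quadratic
        roots = np.roots([1.0, kd_anti + s - a, -a * kd_anti])
        a_free = max(roots)
        assert free_anti == pytest.approx(a_free, rel=1e-10)
        assert complex_ + free_sigma == pytest.approx(s, rel=1e-12)
        assert ctx.molar_to_counts(complex_) == pytest.approx(4993.6995, abs=1e-3)

    def test_conservation_to_machine_precision(self):
        free_sigma, free_anti, complex_ = sc.anti_sigma_partition(
            4e-6, 7e-6, 3e-8, 2e-7, 1e-9, holo_factor=2.5)
        holo = free_sigma * (2e-7 / 1e-9) * 2.5
        assert free_sigma + holo + complex_ == pytest.approx(4e-6, rel=1e-12)
        assert free_anti + complex_ == pytest.approx(7e-6, rel=1e-12)


class TestSolveFreeBinding:
    def test_empty_species_is_usage_error(self, ctx):
        with pytest.raises(sc.UsageError):
            sc.solve_free_binding((), sc.CorePool(100.0), ctx)

    def test_equal_totals_equal_kds_share_equally(self, ctx):
        species = (sc.SigmaSpecies("a", 5700.0), sc.SigmaSpecies("b", 5700.0))
        state = sc.solve_free_binding(species, sc.CorePool(11400.0), ctx)
        ha, hb = state.pools["a"].free_holo, state.pools["b"].free_holo
        assert abs(ha - hb) <= 1e-9 * ha

    def test_single_species_matches_closed_form(self, ctx):
        state = sc.solve_free_binding(
            (sc.SigmaSpecies("s", 5700.0, kd_core=2e-9),),
            sc.CorePool(11400.0), ctx)
        h = sc.holoenzyme_single(ctx.counts_to_molar(11400.0),
                                 ctx.counts_to_molar(5700.0), 2e-9)
        assert state.pools["s"].free_holo == pytest.approx(
            ctx.molar_to_counts(h), rel=1e-10)

    def test_strong_binding_proportional_allocation(self, ctx):
        species = (sc.SigmaSpecies("s70", 5700.0, kd_core=1e-13),
                   sc.SigmaSpecies("alt", 8000.0, kd_core=1e-13))
        state = sc.solve_free_binding(species, sc.CorePool(11400.0), ctx)
        assert state.pools["s70"].free_holo == pytest.approx(
            11400.0 * 5700.0 / 13700.0, rel=1e-6)
        assert state.pools["alt"].free_holo == pytest.approx(
            11400.0 * 8000.0 / 13700.0, rel=1e-6)

    def test_degenerate_totals_give_all_zero_holoenzymes(self, ctx):
        state = sc.solve_free_binding(
            (sc.SigmaSpecies("s", 0.0),), sc.CorePool(0.0), ctx)
        assert state.pools["s"].free_holo == 0.0
        assert state.free_core == 0.0

    def test_species_order_permutation_is_exact(self, ctx):
        a = sc.SigmaSpecies("a", 4000.0, kd_core=0.7e-9)
        b = sc.SigmaSpecies("b", 9000.0, kd_core=3e-9)
        c = sc.SigmaSpecies("c", 1500.0, kd_core=1e-8)
        s1 = sc.solve_free_binding((a, b, c), sc.CorePool(11400.0), ctx)
        s2 = sc.solve_free_binding((c, a, b), sc.CorePool(11400.0), ctx)
        for name in ("a", "b", "c"):
            assert s1.pools[name].free_holo == s2.pools[name].free_holo
            assert s1.pools[name].free_sigma == s2.pools[name].free_sigma

    def test_conservation_residuals_tiny(self, ctx):
        species = (sc.SigmaSpecies("a", 5700.0, kd_core=1e-9,
                                   anti_total=5000.0, kd_anti=1e-11),
                   sc.SigmaSpecies("b", 8000.0, kd_core=5e-9))
        state = sc.solve_free_binding(species, sc.CorePool(11400.0), ctx)
        assert all(r < 1e-9 for r in state.residuals.values())

    def test_holo70_monotone_in_competitor_total(self, ctx, fig2a_scenario):
        grid = np.linspace(0.0, 20000.0, 41)
        h70, halt = [], []
        for alt in grid:
            state = fig2a_scenario(alt).solve()
            h70.append(state.pools["sigma70"].free_holo)
            halt.append(state.pools["sigmaAlt"].free_holo)
        assert np.all(np.diff(h70) <= 1e-9)
        assert np.all(np.diff(halt) >= -1e-9)

    def test_matches_mass_action_ode_steady_state(self, ctx):
        """Oracle equivalence on 20 random small instances (rel 1e-6)."""
        rng = np.random.default_rng(20140)
        for _ in range(20):
            n = rng.integers(1, 4)
            species_params = [
                {"total": ctx.counts_to_molar(rng.uniform(500, 15000)),
                 "kd": 10.0 ** rng.uniform(-10, -8),
                 "kon": 10.0 ** rng.uniform(7, 8.5)}
                for _ in range(n)]
            core_molar = ctx.counts_to_molar(rng.uniform(1000, 15000))
            ode = free_binding_ode(species_params, core_molar, t_end=1e6)
            species = tuple(
                sc.SigmaSpecies(f"s{i}", ctx.molar_to_counts(p["total"]),
                                kd_core=p["kd"])
                for i, p in enumerate(species_params))
            state = sc.solve_free_binding(
                species, sc.CorePool(ctx.molar_to_counts(core_molar)), ctx)
            scale = core_molar
            assert state.context.counts_to_molar(state.free_core) == pytest.approx(
                ode["free_core"], rel=1e-6, abs=1e-6 * scale)
            for i, name in enumerate(state.species_names):
                p = state.pools[name]
                assert ctx.counts_to_molar(p.free_holo) == pytest.approx(
                    ode["holo"][i], rel=1e-6, abs=1e-6 * scale)
                assert ctx.counts_to_molar(p.free_sigma) == pytest.approx(
                    ode["free_sigma"][i], rel=1e-6, abs=1e-6 * scale)

    def test_anti_sigma_against_ode_oracle(self, ctx):
        species_params = [{"total": ctx.counts_to_molar(5000.0), "kd": 1e-9,
                           "kon": 1e8,
                           "anti_total": ctx.counts_to_molar(4000.0),
                           "kd_anti": 1e-10}]
        core_molar = ctx.counts_to_molar(3000.0)
        ode = free_binding_ode(species_params, core_molar, t_end=1e7)
        state = sc.solve_free_binding(
            (sc.SigmaSpecies("s", 5000.0, kd_core=1e-9, anti_total=4000.0,
                             kd_anti=1e-10),),
            sc.CorePool(3000.0), ctx)
        assert ctx.counts_to_molar(state.pools["s"].free_holo) == pytest.approx(
            ode["holo"][0], rel=1e-6)
        assert ctx.counts_to_molar(state.pools["s"].anti_bound_sigma) == \
            pytest.approx(ode["anti_complex"][0], rel=1e-6)


class TestStrongBindingPartition:
    def test_excess_core_binds_every_sigma(self):
        out = sc.strong_binding_partition([3.0, 4.0], 10.0, [1.0, 2.0])
        assert out == pytest.approx([3.0, 4.0])

    def test_equal_ratios_give_proportional_allocation(self):
        out = sc.strong_binding_partition([5700.0, 8000.0], 11400.0, [1.0, 1.0])
        assert out == pytest.approx(
            [11400.0 * 5700.0 / 13700.0, 11400.0 * 8000.0 / 13700.0], rel=1e-12)

    def test_total_bound_equals_core_in_deficit(self):
        out = sc.strong_binding_partition(
            [4.0, 9.0, 2.0], 10.0, [1.0, 3.0, 0.2])
        assert out.sum() == pytest.approx(10.0, rel=1e-12)
        assert np.all(out >= 0) and np.all(out <= [4.0, 9.0, 2.0])

    def test_matches_full_solver_with_scaled_down_kds(self, ctx):
        """The limit of the general solver as kds shrink at fixed ratios."""
        rel = np.array([1.0, 2.5, 17.0])
        totals = np.array([9000.0, 5000.0, 3000.0])
        limit = sc.strong_binding_partition(totals, 11400.0, rel)
        species = tuple(
            sc.SigmaSpecies(f"s{i}", totals[i], kd_core=1e-13 * rel[i])
            for i in range(3))
        state = sc.solve_free_binding(species, sc.CorePool(11400.0), ctx)
        for i in range(3):
            assert state.pools[f"s{i}"].free_holo == pytest.approx(
                limit[i], rel=1e-6)
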