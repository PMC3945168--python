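"""Age-structured progenitor compartment: rates, transport, steady states."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dediffsim import progenitor as pg
from dediffsim.progenitor import (
    AgeDensity,
    EmptyPopulationError,
    ProgenitorParams,
    ProgenitorPDE,
    advance,
    birth_rate,
    chi_sweep,
    death_rate,
    mutant_fraction,
    steady_state_cascade,
    steady_state_profile,
    subpopulation_total,
)


class TestRates:
    def test_birth_half_maximum_at_switch_age(self, default_progenitor_params):
        p = default_progenitor_params
        assert birth_rate(p.birth_switch_age, 0, p) == pytest.approx(0.75)
        assert birth_rate(0.0, 0, p) == pytest.approx(1.5)
        # per-mutation advantage: 1.5 + 0.2 k at the default advantage
        assert birth_rate(0.0, 1, p) == pytest.approx(1.7)
        assert birth_rate(0.0, 2, p) == pytest.approx(1.9)

    def test_zero_steepness_gives_uniform_rate(self):
        p = ProgenitorParams(birth_steepness=0.0, death_steepness=0.0)
        ages = np.linspace(0, p.max_age, 7)
        b = birth_rate(ages, 0, p)
        d = death_rate(ages, p)
        assert np.allclose(b, b[0]) and b[0] == pytest.approx(0.75)
        assert np.allclose(d, d[0]) and d[0] == pytest.approx(0.5)

    def test_birth_monotone_decreasing_death_increasing(self):
        p = ProgenitorParams(death_switch_age=5.0)
        ages = np.linspace(0, p.max_age, 50)
        b = birth_rate(ages, 2, p)
        d = death_rate(ages, p)
        assert np.all(np.diff(b) <= 0) and b[0] > b[-1]
        assert np.all(np.diff(d) >= 0)

    def test_default_death_rate_constant_beyond_zero(self, default_progenitor_params):
        p = default_progenitor_params
        assert death_rate(0.0, p) == pytest.approx(0.5)  # half-max at switch age
        assert death_rate(1.0, p) == pytest.approx(1.0)
        assert death_rate(20.0, p) == pytest.approx(1.0)

    def test_domain_errors(self, default_progenitor_params):
        p = default_progenitor_params
        with pytest.raises(ValueError):
            birth_rate(-1.0, 0, p)
        with pytest.raises(ValueError):
            birth_rate(1.0, 3, p)
        with pytest.raises(ValueError):
            death_rate(-0.5, p)

    @given(
        a=st.floats(0, 20),
        switch=st.floats(0.5, 15),
        m=st.floats(0.0, 6.0),
    )
    def test_birth_rate_bounded_by_maximum(self, a, switch, m):
        p = ProgenitorParams(birth_switch_age=switch, birth_steepness=m)
        b = birth_rate(a, 0, p)
        assert 0.0 <= b <= p.birth_max[0]


class TestAdvance:
    def test_pure_advection_shifts_density(self):
        p = ProgenitorParams(
            birth_max=(0.0, 0.0, 0.0), death_max=0.0, mutation_rate=0.0,
            age_step=0.5,
        )
        state = AgeDensity.zero(p)
        state.density[0, :] = np.linspace(1.0, 2.0, state.grid.size)
        before = state.density[0].copy()
        new = advance(state, (0.0, 0.0, 0.0), p.age_step, p)
        assert np.allclose(new.density[0, 1:], before[:-1])
        assert new.density[0, 0] == 0.0
        # mass reduced only by outflow at the maximum age
        lost = np.trapezoid(before, dx=0.5) - np.trapezoid(new.density[0], dx=0.5)
        assert lost == pytest.approx(0.5 * (before[-2] / 2 + before[-1] / 2), rel=0.35)

    def test_wrong_dt_rejected(self, default_progenitor_params):
        state = AgeDensity.zero(default_progenitor_params)
        with pytest.raises(ValueError):
            advance(state, (0, 0, 0), 0.123, default_progenitor_params)

    def test_long_run_matches_steady_wave_form(self):
        """Transport + net growth converges to the exponential wave profile,
        with first-order accuracy in the age step."""
        def rel_error(da):
            p = ProgenitorParams(age_step=da, mutation_rate=0.0)
            pde = ProgenitorPDE(p)
            influx = (5.0, 1.0, 0.0)
            n = np.zeros((3, p.ages.size))
            for _ in range(int(2.5 * p.max_age / da)):
                n = pde.step(n, influx)
            exact = steady_state_profile(p, influx).density
            return np.max(np.abs(n - exact)) / exact.max()

        e_coarse, e_fine = rel_error(0.2), rel_error(0.1)
        assert e_fine < e_coarse
        assert e_coarse / e_fine == pytest.approx(2.0, abs=0.5)

    def test_mutation_cascade_orders_subpopulations(self):
        p = ProgenitorParams(age_step=0.1, mutation_rate=1e-3)
        pde = ProgenitorPDE(p)
        n = np.zeros((3, p.ages.size))
        for _ in range(int(3 * p.max_age / p.age_step)):
            n = pde.step(n, (5.0, 0.0, 0.0))
        state = AgeDensity(grid=p.ages, density=n)
        totals = state.totals()
        assert 0 < totals[2] < totals[1] < totals[0]
        # agrees with the analytic cascade steady state (the first-order
        # reaction bias compounds once per mutation step, so the class-2
        # total carries the largest discretization error)
        exact = steady_state_cascade(p, (5.0, 0.0, 0.0)).totals()
        assert totals == pytest.approx(exact, rel=0.2)

    def test_mass_balance_each_step(self):
        p = ProgenitorParams(age_step=0.1, mutation_rate=1e-3)
        pde = ProgenitorPDE(p)
        n = steady_state_profile(
            ProgenitorParams(age_step=0.1, mutation_rate=0.0), (5.0, 0.0, 0.0)
        ).density.copy()
        da = p.age_step
        for _ in range(40):
            before = np.trapezoid(n.sum(axis=0), dx=da)
            influx = (5.0, 0.0, 0.0)
            growth = ((pde.birth - pde.death) * n).sum(axis=0)
            rate_gain = np.trapezoid(growth, dx=da)
            outflow = n.sum(axis=0)[-1]
            n = pde.step(n, influx)
            after = np.trapezoid(n.sum(axis=0), dx=da)
            predicted = before + (rate_gain + sum(influx) - outflow) * da
            assert after == pytest.approx(predicted, abs=30 * da * da + 1e-9)

    def test_negative_density_guard(self):
        p = ProgenitorParams(
            birth_max=(0.0, 0.0, 0.0), death_max=30.0, age_step=0.1,
            mutation_rate=0.0,
        )
        pde = ProgenitorPDE(p)
        n = np.ones((3, p.ages.size))
        with pytest.raises(pg.NumericalStabilityError):
            pde.step(n, (0.0, 0.0, 0.0))


class TestSteadyState:
    def test_birth_equals_death_gives_flat_profile(self):
        p = ProgenitorParams(
            birth_max=(1.0, 1.0, 1.0), birth_steepness=0.0,
            death_max=1.0, death_steepness=0.0, mutation_rate=0.0,
        )
        st_ = steady_state_profile(p, (3.0, 0.0, 0.0))
        assert np.allclose(st_.density[0], 3.0)

    def test_logistic_large_capacity_matches_unbounded(self):
        p0 = ProgenitorParams(mutation_rate=0.0)
        pl = ProgenitorParams(
            mutation_rate=0.0, competition_mode="logistic", carrying_capacity=1e12
        )
        a = steady_state_profile(p0, (5.0, 0.0, 0.0)).density
        b = steady_state_profile(pl, (5.0, 0.0, 0.0)).density
        assert np.allclose(a, b, rtol=1e-6)

    def test_logistic_caps_total(self):
        K = 50.0
        pl = ProgenitorParams(
            mutation_rate=0.0, competition_mode="logistic", carrying_capacity=K
        )
        st_ = steady_state_profile(pl, (5.0, 0.0, 0.0))
        total = st_.totals()[0]
        unbounded = steady_state_profile(
            ProgenitorParams(mutation_rate=0.0), (5.0, 0.0, 0.0)
        ).totals()[0]
        assert total < unbounded
        assert total < unbounded  # saturation
        assert total == pytest.approx(
            np.trapezoid(st_.density[0], dx=pl.age_step), rel=1e-12
        )

    def test_competition_modes_converge_to_none_at_large_K(self):
        p0 = ProgenitorParams(age_step=0.1, mutation_rate=0.0)
        base = steady_state_profile(p0, (5.0, 0.0, 0.0)).density
        for mode in ("logistic", "local", "global"):
            p = ProgenitorParams(
                age_step=0.1, mutation_rate=0.0,
                competition_mode=mode, carrying_capacity=1e12,
            )
            pde = ProgenitorPDE(p)
            n = base.copy()
            for _ in range(200):
                n = pde.step(n, (5.0, 0.0, 0.0))
            # stays at the no-competition steady state
            ref = ProgenitorPDE(p0)
            m = base.copy()
            for _ in range(200):
                m = ref.step(m, (5.0, 0.0, 0.0))
            assert np.allclose(n, m, rtol=1e-6, atol=1e-9)


class TestDiagnostics:
    def test_mutant_fraction_forced_cases(self, default_progenitor_params):
        p = default_progenitor_params
        state = AgeDensity.zero(p)
        state.density[2, :] = 1.0
        assert mutant_fraction(state) == pytest.approx(1.0)
        state.density[0, :] = 1.0
        state.density[1, :] = 1.0
        assert mutant_fraction(state) == pytest.approx(1.0 / 3.0)
        state.density[2, :] = 0.0
        assert mutant_fraction(state) < 1e-12

    def test_mutant_fraction_empty_population_errors(self, default_progenitor_params):
        with pytest.raises(EmptyPopulationError):
            mutant_fraction(AgeDensity.zero(default_progenitor_params))

    def test_subpopulation_total_uniform(self, default_progenitor_params):
        p = default_progenitor_params
        state = AgeDensity.zero(p)
        state.density[1, :] = 2.5
        assert subpopulation_total(state, 1) == pytest.approx(2.5 * p.max_age)
        assert subpopulation_total(state, 0) == 0.0

    def test_total_stable_under_grid_refinement(self):
        totals = []
        for da in (0.1, 0.05):
            p = ProgenitorParams(age_step=da, mutation_rate=0.0)
            st_ = steady_state_profile(p, (5.0, 0.0, 0.0))
            totals.append(st_.totals()[0])
        # the death-rate switch at age 0 makes the quadrature first-order
        # in the age step near the boundary
        assert totals[0] == pytest.approx(totals[1], rel=2e-2)

    def test_chi_sweep_monotone_in_v_and_s(self):
        df = chi_sweep(
            [1e-4, 1e-3, 1e-2], [0.0, 0.2, 0.5], influx0=5.0,
            base_params=ProgenitorParams(age_step=0.1),
        )
        grid = df.pivot(index="v", columns="s", values="chi").to_numpy()
        assert np.all(np.diff(grid, axis=0) > 0)  # increasing in v
        assert np.all(np.diff(grid, axis=1) > 0)  # increasing in s


@given(
    da=st.sampled_from([0.1, 0.2, 0.25]),
    v=st.floats(0.0, 0.05),
    flux=st.floats(0.0, 10.0),
)
def test_densities_never_negative(da, v, flux):
    p = ProgenitorParams(age_step=da, mutation_rate=v)
    pde = ProgenitorPDE(p)
    n = np.zeros((3, p.ages.size))
    for _ in range(60):
        n = pde.step(n, (flux, 0.0, flux / 2))
    assert n.min() >= 0.0


def test_parameter_validation():
    with pytest.raises(ValueError):
        ProgenitorParams(max_age=-1)
    with pytest.raises(ValueError):
        ProgenitorParams(max_age=1.0, age_step=0.3)
    with pytest.raises(ValueError):
        ProgenitorParams(competition_mode="tournament")
    with pytest.raises(ValueError):
        ProgenitorParams(mutation_rate=-1e-5)
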