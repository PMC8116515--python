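"""Patient-journey model: transition arithmetic, initialization anchors,
an independent step-by-step oracle, and population-level invariants."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from t2dsim.engine import SimulationClock, integrate
from t2dsim.journey import (
    CUM_DEATHS, CUM_INFLOW, DIAG, NORMO, PERSON_STOCKS, T2DM, UNDIAG,
    NORMO_BACKGROUND, PREDIABETES_POOL,
    ConfigurationError, JourneyParameters, JourneyState, Transition,
    build_journey_system, death_rate, diagnosis_split, initialize_state,
    journey_derivatives, prediabetes_onset, transition_rate,
)


class TestTransitionRate:
    @pytest.mark.parametrize(
        "stock,fraction,years,expected",
        [
            (0.0, 0.5, 3.0, 0.0),
            (1200.0, 0.70, 4.0, 17.5),  # diagnosed pre-diabetics -> T2DM row
            (1000.0, 0.01, 3.0, 1000 * 0.01 / 36),  # baseline T2DM recovery row
        ],
    )
    def test_examples(self, stock, fraction, years, expected):
        assert transition_rate(stock, fraction, years) == pytest.approx(expected, rel=1e-12)

    def test_linear_in_stock(self):
        assert transition_rate(2400.0, 0.3, 2.0) == pytest.approx(
            2 * transition_rate(1200.0, 0.3, 2.0)
        )

    @pytest.mark.parametrize("bad_time", [0.0, -1.0])
    def test_nonpositive_time_rejected(self, bad_time):
        with pytest.raises(ConfigurationError):
            transition_rate(100.0, 0.5, bad_time)


class TestOnsetAndDiagnosis:
    def test_onset_examples(self, journey_params):
        assert prediabetes_onset(0.0, 0.51, journey_params) == 0.0
        assert prediabetes_onset(1_000_000, 0.0, journey_params) == pytest.approx(
            1_000_000 * 0.01 / 24, rel=1e-12
        )
        # two-compartment split at the published overweight share
        expected = 490_000 * 0.01 / 24 + 510_000 * 0.33 / 36
        assert prediabetes_onset(1_000_000, 0.51, journey_params) == pytest.approx(
            expected, rel=1e-12
        )

    def test_diagnosis_split_examples(self):
        assert diagnosis_split(100.0, 0.2, 0.1) == pytest.approx((30.0, 70.0))
        assert diagnosis_split(100.0, 0.0, 0.0) == (0.0, 100.0)

    @given(
        onset=st.floats(0.0, 1e6),
        ifg=st.floats(0.0, 0.6),
        igt=st.floats(0.0, 0.4),
    )
    def test_split_conserves_onset(self, onset, ifg, igt):
        diagnosed, undiagnosed = diagnosis_split(onset, ifg, igt)
        assert diagnosed + undiagnosed == pytest.approx(onset, rel=1e-12, abs=1e-12)
        assert diagnosed >= 0 and undiagnosed >= 0

    def test_overfull_split_rejected(self):
        with pytest.raises(ConfigurationError):
            diagnosis_split(100.0, 0.7, 0.4)


class TestDeathRate:
    def test_exact_division_example(self):
        # 872,400 patients over 72.7 years x 12 months -> 1000 per month
        assert death_rate(872_400.0, 72.7) == pytest.approx(1000.0, rel=1e-12)

    def test_remaining_life_by_stock(self, journey_params):
        assert journey_params.remaining_life(UNDIAG) == pytest.approx(71.7)
        assert journey_params.remaining_life(DIAG) == pytest.approx(73.7)
        assert journey_params.remaining_life(T2DM) == pytest.approx(72.7)
        assert journey_params.remaining_life(NORMO) == pytest.approx(81.7)

    def test_zero_stock(self):
        assert death_rate(0.0, 72.7) == 0.0


class TestInitializeState:
    def test_anchor_and_population_closure(self, journey_params, clock):
        state = initialize_state(journey_params, clock)
        assert state.t2dm == pytest.approx(144_000.0)  # 160,000 DM x 0.9
        assert state.total_persons == pytest.approx(
            journey_params.population(1990), rel=1e-12
        )

    def test_zero_anchor_all_normoglycemic(self, journey_params, clock):
        params = replace(journey_params, anchor_t2dm=0.0)
        state = initialize_state(params, clock)
        assert state.t2dm == 0.0
        assert state.normoglycemic == pytest.approx(
            params.population(1990), rel=1e-12
        )

    def test_steady_state_seeding_variant(self, journey_params, clock):
        """With the seed scale at 1, the pre-diabetic stocks start at their
        analytic steady-state shares of the normoglycemic stock."""
        params = replace(journey_params, initial_prediabetic_scale=1.0)
        state = initialize_state(params, clock)
        w = params.rapid_share_at(1990)
        onset = w * 0.33 / 3 + (1 - w) * 0.01 / 2  # per normoglycemic, per year
        out_u = 0.90 / 7 + 0.10 / 4 + 1 / 71.7
        out_d = 0.70 / 4 + 0.30 / 2 + 1 / 73.7
        assert state.undiagnosed_prediabetic == pytest.approx(
            state.normoglycemic * 0.5 * onset / out_u, rel=1e-9
        )
        assert state.diagnosed_prediabetic == pytest.approx(
            state.normoglycemic * 0.5 * onset / out_d, rel=1e-9
        )
        assert state.total_persons == pytest.approx(
            params.population(1990), rel=1e-12
        )

    def test_oversized_anchor_rejected(self, journey_params, clock):
        params = replace(journey_params, anchor_t2dm=1e9)
        with pytest.raises(ConfigurationError):
            initialize_state(params, clock)


class TestDerivatives:
    def test_reachability_from_pure_normoglycemic(self, journey_params):
        state = JourneyState(normoglycemic=1_000_000.0)
        rates = journey_derivatives(state, journey_params, t_months=0.0)
        nonzero = {name for name, r in rates.items() if r != 0.0}
        expected_nonzero = {
            "prediabetes_onset_diagnosed", "prediabetes_onset_undiagnosed",
            "deaths_normoglycemic", "demographic_replenishment",
            "demographic_inflow_tracker",
        }
        assert nonzero == expected_nonzero

    def test_all_fractions_zero_freezes_interstock_flows(self, journey_params):
        transitions = {
            key: Transition(0.0, tr.avg_time_years)
            for key, tr in journey_params.transitions.items()
        }
        params = replace(
            journey_params, transitions=transitions, relapse=Transition(0.0, 2.0)
        )
        state = JourneyState(
            normoglycemic=1e6, undiagnosed_prediabetic=1e4,
            diagnosed_prediabetic=1e4, t2dm=1e5, no_medicine_necessary=1e3,
        )
        rates = journey_derivatives(state, params, t_months=0.0)
        interstock = [
            "prediabetes_onset_diagnosed", "prediabetes_onset_undiagnosed",
            "diagnosed_to_t2dm", "undiagnosed_to_t2dm", "diagnosed_recovery",
            "undiagnosed_recovery", "t2dm_baseline_recovery", "relapse",
        ]
        for name in interstock:
            assert rates[name] == 0.0


def _oracle_one_year(state0, population):
    """Independent spreadsheet-style stepper: twelve monthly Euler steps of
    the journey written out literally from the published parameter table
    (50:50 diagnosis split, deaths excluded, constant population)."""
    n, u, d, t, m = state0
    for _ in range(12):
        onset = (0.998 * n) * 0.01 / 24 + (0.002 * n) * 0.33 / 36
        onset_diag, onset_undiag = 0.5 * onset, 0.5 * onset
        d_to_t = d * 0.70 / 48
        u_to_t = u * 0.90 / 84
        d_to_n = d * 0.30 / 24
        u_to_n = u * 0.10 / 48
        t_to_n = t * 0.01 / 36
        relapse = m * 0.65 / 24
        sustain = m * 0.35 / 24
        repl = population - (n + u + d + t + m)  # dt = 1 month
        n = n + repl + d_to_n + u_to_n + t_to_n + sustain - onset
        u = u + onset_undiag - u_to_t - u_to_n
        d = d + onset_diag - d_to_t - d_to_n
        t = t + d_to_t + u_to_t + relapse - t_to_n
        m = m + 0.0 - relapse - sustain
    return n, u, d, t, m


def test_one_year_trajectory_matches_independent_oracle():
    """A twelve-month Euler run of the journey (constant population, deaths
    disabled) agrees with an independently coded step-by-step oracle."""
    n0, u0, d0, t0, m0 = 1e6, 5e4, 3e4, 2e4, 1e4
    population = n0 + u0 + d0 + t0 + m0
    params = JourneyParameters(
        population_trend={1990: population, 2000: population},
        healthy_life_expectancy=1e12,  # deaths negligible over one year
        lifespan_shortening={UNDIAG: 10.0, DIAG: 8.0, T2DM: 9.0},
        anchor_t2dm=t0,
    )
    clock = SimulationClock(1990, 1991, 1.0)
    initial = JourneyState(
        normoglycemic=n0, undiagnosed_prediabetic=u0,
        diagnosed_prediabetic=d0, t2dm=t0, no_medicine_necessary=m0,
    )
    system = build_journey_system(params, clock, initial=initial)
    traj = integrate(system, clock)
    expected = _oracle_one_year((n0, u0, d0, t0, m0), population)
    for name, value in zip(PERSON_STOCKS, expected):
        assert traj.stocks[name][12] == pytest.approx(value, rel=1e-9), name


class TestInvariants:
    def test_population_conservation_over_full_run(self, baseline_result):
        """Total persons + cumulative deaths - cumulative demographic inflow
        stays within one person of the initial total over 46 years."""
        tr = baseline_result.trajectory
        total = sum(tr.stocks[s] for s in PERSON_STOCKS)
        balance = total + tr.stocks[CUM_DEATHS] - tr.stocks[CUM_INFLOW]
        assert np.max(np.abs(balance - balance[0])) < 1.0

    def test_monotone_response_to_onset_fraction(self, journey_params, cost_params):
        from t2dsim.scenarios import Scenario, run_scenario

        clock = SimulationClock(1990, 2010, 1.0)
        def t2dm_series(background_fraction):
            transitions = dict(journey_params.transitions)
            transitions[(NORMO_BACKGROUND, PREDIABETES_POOL)] = Transition(
                background_fraction, 2.0
            )
            params = replace(journey_params, transitions=transitions)
            result = run_scenario(Scenario("x", []), params, cost_params, clock)
            return result.trajectory.stocks[T2DM]

        low, high = t2dm_series(0.01), t2dm_series(0.02)
        assert np.all(high >= low - 1e-9)
        assert high[-1] > low[-1]

    def test_monotone_response_to_recovery_fraction(self, journey_params, cost_params):
        from t2dsim.scenarios import Scenario, run_scenario

        clock = SimulationClock(1990, 2010, 1.0)
        def t2dm_series(recovery_fraction):
            transitions = dict(journey_params.transitions)
            transitions[(T2DM, NORMO)] = Transition(recovery_fraction, 3.0)
            params = replace(journey_params, transitions=transitions)
            result = run_scenario(Scenario("x", []), params, cost_params, clock)
            return result.trajectory.stocks[T2DM]

        low, high = t2dm_series(0.01), t2dm_series(0.10)
        assert np.all(high <= low + 1e-9)
        assert high[-1] < low[-1]

    def test_reinforcing_structure_without_recovery(self, journey_params, cost_params):
        """With all recovery fractions zero, positive onset makes the T2DM
        stock non-decreasing (deaths excluded to isolate the loop)."""
        from t2dsim.scenarios import Scenario, run_scenario

        transitions = dict(journey_params.transitions)
        for key in [(DIAG, NORMO), (UNDIAG, NORMO), (T2DM, NORMO)]:
            transitions[key] = Transition(0.0, transitions[key].avg_time_years)
        params = replace(
            journey_params, transitions=transitions, healthy_life_expectancy=1e9
        )
        clock = SimulationClock(1990, 2010, 1.0)
        result = run_scenario(Scenario("x", []), params, cost_params, clock)
        t2dm = result.trajectory.stocks[T2DM]
        # tolerance covers the residual (negligible but nonzero) mortality
        assert np.all(np.diff(t2dm) >= -1e-3)

    def test_default_growth_is_monotone_through_2019(self, baseline_result, clock):
        """Annual T2DM counts rise every year from 1990 through 2019."""
        annual = np.array([
            baseline_result.trajectory.stocks[T2DM][clock.year_start_index(y)]
            for y in range(1990, 2020)
        ])
        assert np.all(np.diff(annual) > 0)
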