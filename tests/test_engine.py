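"""Forward-Euler stock-flow engine: conservation, closed-form oracles,
clamping, determinism and validation errors."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from t2dsim.engine import (
    EXTERNAL, EngineError, Flow, SimulationClock, StockFlowSystem,
    euler_step, evaluate_rates, integrate,
)
from t2dsim.fixtures import toy_system


def make_clock(months, dt=1.0):
    # smallest inclusive-year horizon covering `months`
    years = max(2, math.ceil(months / 12))
    return SimulationClock(1990, 1990 + years - 1, dt)


class TestEulerStep:
    def test_zero_rate_identity(self):
        flows = [Flow("out", "S", EXTERNAL, lambda s, t: 0.0)]
        state, clamps = euler_step({"S": 100.0}, {"out": 0.0}, flows, 1.0)
        assert state == {"S": 100.0}
        assert clamps == []

    @given(
        a0=st.floats(0.0, 1e6),
        b0=st.floats(0.0, 1e6),
        rate=st.floats(0.0, 1e4),
        dt=st.floats(0.1, 12.0),
    )
    def test_two_stock_transfer_conserves_total(self, a0, b0, rate, dt):
        flows = [Flow("move", "A", "B", lambda s, t: rate)]
        state, _ = euler_step({"A": a0, "B": b0}, {"move": rate}, flows, dt)
        # conservation holds exactly up to clamping of an overdrawn source
        if a0 - dt * rate >= 0:
            assert state["A"] + state["B"] == pytest.approx(a0 + b0, rel=1e-12)

    def test_nonfinite_rate_names_the_flow(self):
        flows = [Flow("bad_flow", "S", EXTERNAL, lambda s, t: float("nan"))]
        with pytest.raises(EngineError, match="bad_flow"):
            evaluate_rates({"S": 1.0}, flows, 0.0)
        with pytest.raises(EngineError, match="bad_flow"):
            euler_step({"S": 1.0}, {"bad_flow": float("inf")}, flows, 1.0)

    def test_clamp_at_zero_is_logged(self):
        flows = [Flow("drain", "S", EXTERNAL, lambda s, t: 10.0)]
        state, clamps = euler_step({"S": 5.0}, {"drain": 10.0}, flows, 1.0)
        assert state["S"] == 0.0
        assert len(clamps) == 1
        assert clamps[0].stock == "S"
        assert clamps[0].deficit == pytest.approx(5.0)

    def test_unclamped_stock_may_go_negative(self):
        flows = [Flow("drain", "S", EXTERNAL, lambda s, t: 10.0)]
        state, clamps = euler_step(
            {"S": 5.0}, {"drain": 10.0}, flows, 1.0, unclamped=frozenset({"S"})
        )
        assert state["S"] == pytest.approx(-5.0)
        assert clamps == []


class TestIntegrate:
    def test_constant_inflow_accumulates_exactly(self):
        k = 7.25
        system = StockFlowSystem(
            stocks={"S": 10.0},
            flows=[Flow("in", EXTERNAL, "S", lambda s, t: k)],
        )
        clock = make_clock(24)
        traj = integrate(system, clock)
        n = clock.n_steps
        assert traj.stocks["S"][-1] == pytest.approx(10.0 + n * clock.dt_months * k, rel=1e-14)

    def test_empty_flow_set_keeps_stocks_constant(self):
        system = StockFlowSystem(stocks={"A": 3.0, "B": 0.5}, flows=[])
        traj = integrate(system, make_clock(36))
        assert np.all(traj.stocks["A"] == 3.0)
        assert np.all(traj.stocks["B"] == 0.5)

    def test_decay_matches_exponential_within_euler_bound(self):
        system, oracle = toy_system("decay")
        tau, s0, horizon = 24.0, 1000.0, 24.0
        clock = make_clock(horizon)
        traj = integrate(system, clock)
        idx = round(horizon / clock.dt_months)
        exact = oracle(horizon)["S"]
        # global-error bound for forward Euler on S' = -S/tau
        bound = (clock.dt_months * s0 / (2 * tau)) * (math.exp(horizon / tau) - 1)
        assert abs(traj.stocks["S"][idx] - exact) < bound

    def test_decay_error_shrinks_as_dt_halves(self):
        _, oracle = toy_system("decay")
        exact = oracle(24.0)["S"]
        errors = []
        for dt in (1.0, 0.5, 0.25):
            system, _ = toy_system("decay")
            clock = make_clock(24, dt)
            traj = integrate(system, clock)
            errors.append(abs(traj.stocks["S"][round(24 / dt)] - exact))
        assert errors[0] > errors[1] > errors[2]

    def test_logistic_population_levels_off_below_capacity(self):
        system, oracle = toy_system("logistic_population")
        clock = make_clock(552)
        traj = integrate(system, clock)
        p = traj.stocks["P"]
        k = 10_000.0
        assert np.all(np.diff(p) >= 0), "growth must be monotone"
        assert np.all(p <= k + 1e-9), "population must not exceed carrying capacity"
        assert p[-1] == pytest.approx(k, rel=0.01)
        # births approach deaths at equilibrium
        assert traj.flows["births"][-1] == pytest.approx(traj.flows["deaths"][-1], rel=0.01)

    def test_deterministic_bit_identical(self):
        def build():
            return StockFlowSystem(
                stocks={"A": 500.0, "B": 1.0},
                flows=[
                    Flow("move", "A", "B", lambda s, t: s["A"] / 36.0),
                    Flow("leak", "B", EXTERNAL, lambda s, t: s["B"] / 120.0),
                ],
            )
        clock = make_clock(120)
        t1 = integrate(build(), clock)
        t2 = integrate(build(), clock)
        for name in t1.stocks:
            assert np.array_equal(t1.stocks[name], t2.stocks[name])
        for name in t1.flows:
            assert np.array_equal(t1.flows[name], t2.flows[name])

    @given(
        a0=st.floats(10.0, 1e5),
        inflow=st.floats(0.0, 100.0),
        tau=st.floats(6.0, 120.0),
    )
    def test_mass_balance_against_external_flows(self, a0, inflow, tau):
        """Per step, the change in total stock equals dt x net external flow."""
        system = StockFlowSystem(
            stocks={"A": a0, "B": 0.0},
            flows=[
                Flow("in", EXTERNAL, "A", lambda s, t: inflow),
                Flow("move", "A", "B", lambda s, t: s["A"] / tau),
                Flow("out", "B", EXTERNAL, lambda s, t: s["B"] / tau),
            ],
        )
        clock = make_clock(24)
        traj = integrate(system, clock)
        total = traj.stocks["A"] + traj.stocks["B"]
        net_external = traj.flows["in"] - traj.flows["out"]
        assert np.allclose(
            np.diff(total), clock.dt_months * net_external, rtol=1e-12, atol=1e-9
        )


class TestValidation:
    def test_unresolved_flow_endpoint_rejected(self):
        system = StockFlowSystem(
            stocks={"A": 1.0},
            flows=[Flow("move", "A", "missing", lambda s, t: 0.0)],
        )
        with pytest.raises(EngineError, match="missing"):
            system.validate()

    def test_duplicate_flow_name_rejected(self):
        flow = Flow("f", "A", EXTERNAL, lambda s, t: 0.0)
        system = StockFlowSystem(stocks={"A": 1.0}, flows=[flow, flow])
        with pytest.raises(EngineError, match="duplicate"):
            system.validate()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"start_year": 2000, "end_year": 2000},
            {"start_year": 2000, "end_year": 1990},
            {"dt_months": 0.0},
            {"dt_months": -1.0},
            {"dt_months": 7.0},  # 12 not divisible by 7
        ],
    )
    def test_bad_clock_rejected(self, kwargs):
        with pytest.raises(EngineError):
            SimulationClock(**{"start_year": 1990, "end_year": 2035, **kwargs})

    def test_year_indices(self):
        clock = SimulationClock(1990, 2035, 1.0)
        assert clock.n_steps == 552
        assert clock.year_start_index(1990) == 0
        assert clock.year_index(1990) == 12
        assert clock.year_index(2035) == 552
        with pytest.raises(EngineError):
            clock.year_index(2036)
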