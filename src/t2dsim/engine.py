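"""Deterministic stock-and-flow simulation core.

The classic system-dynamics scheme: a model is a set of named stocks
(accumulations, e.g. persons or euros) connected by flows (rates of change
per month).  Trajectories are produced by forward Euler at a fixed time
step, the integration method of choice of the desktop SD tools this package
mirrors.  Stocks are non-negative; a step that would drive a stock below
zero is clamped at zero and the event is logged.

All rates are *per month*; parameters stated in years must be converted at
configuration load (divide by 12).  Time ``t`` is measured in months since
January of the clock's start year.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: A flow-rate function: (current stock values, time in months) -> persons
#: (or euros) per month.  Must be finite for finite states.
RateFn = Callable[[Mapping[str, float], float], float]

EXTERNAL = None  # source/sink marker for flows crossing the model boundary


class EngineError(ValueError):
    """Raised for ill-formed systems or non-finite flow rates."""


@dataclass(frozen=True)
class SimulationClock:
    """Fixed-step calendar clock.

    The horizon is inclusive of ``end_year``: the run covers January of
    ``start_year`` through December of ``end_year``, so yearly outputs can
    be reported at the end of December of every simulated year, including
    the last one.

    Parameters
    ----------
    start_year, end_year : int
        First and last simulated calendar years.
    dt_months : float
        Time step in months (default 1).  ``(end_year - start_year + 1) * 12``
        must be an integer multiple of ``dt_months``.
    """

    start_year: int = 1990
    end_year: int = 2035
    dt_months: float = 1.0

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise EngineError("end_year must be greater than start_year")
        if not self.dt_months > 0:
            raise EngineError("dt_months must be positive")
        total = (self.end_year - self.start_year + 1) * 12
        steps = total / self.dt_months
        if abs(steps - round(steps)) > 1e-9:
            raise EngineError(
                f"horizon of {total} months is not an integer number of "
                f"steps at dt={self.dt_months}"
            )

    @property
    def n_steps(self) -> int:
        return round((self.end_year - self.start_year + 1) * 12 / self.dt_months)

    def times_months(self) -> np.ndarray:
        """Recorded time points (months since Jan of start_year), length n_steps + 1."""
        return np.arange(self.n_steps + 1) * self.dt_months

    def times_years(self) -> np.ndarray:
        """Recorded time points as decimal calendar years."""
        return self.start_year + self.times_months() / 12.0

    def year_index(self, year: int) -> int:
        """Trajectory index of the end-of-December state of ``year``."""
        self._check_year(year)
        return round((year - self.start_year + 1) * 12 / self.dt_months)

    def year_start_index(self, year: int) -> int:
        """Trajectory index of the 1-January state of ``year``."""
        self._check_year(year)
        return round((year - self.start_year) * 12 / self.dt_months)

    def _check_year(self, year: int) -> None:
        if not self.start_year <= year <= self.end_year:
            raise EngineError(
                f"year {year} outside simulated horizon "
                f"{self.start_year}-{self.end_year}"
            )

    def report_years(self) -> range:
        return range(self.start_year, self.end_year + 1)


@dataclass(frozen=True)
class Flow:
    """A named transfer between two stocks (or across the model boundary).

    ``source``/``sink`` name declared stocks, or ``None`` for the external
    environment ("cloud").  ``rate`` is evaluated on the current state and
    returns a per-month rate.  Rates are normally non-negative; a signed
    rate on a boundary flow is permitted (net migration may be negative).
    """

    name: str
    source: str | None
    sink: str | None
    rate: RateFn


@dataclass
class StockFlowSystem:
    """A set of stocks, flows and exogenous auxiliaries ready to integrate."""

    stocks: dict[str, float]
    flows: Sequence[Flow]
    auxiliaries: dict[str, object] = field(default_factory=dict)
    #: accounting stocks exempt from the non-negativity clamp (e.g. a
    #: cumulative net-migration tracker, which may legitimately be negative)
    unclamped: frozenset[str] = frozenset()

    def validate(self) -> None:
        if not self.stocks:
            raise EngineError("system declares no stocks")
        seen: set[str] = set()
        for f in self.flows:
            if f.name in seen:
                raise EngineError(f"duplicate flow name {f.name!r}")
            seen.add(f.name)
            for end, label in ((f.source, "source"), (f.sink, "sink")):
                if end is not None and end not in self.stocks:
                    raise EngineError(
                        f"flow {f.name!r} {label} {end!r} is not a declared stock"
                    )
            if f.source is None and f.sink is None:
                raise EngineError(f"flow {f.name!r} connects nothing to nothing")
        for name, value in self.stocks.items():
            if not math.isfinite(value) or (value < 0 and name not in self.unclamped):
                raise EngineError(f"initial value of stock {name!r} is {value}")


@dataclass
class ClampEvent:
    """Record of a stock clamped at zero during one Euler step."""

    t_months: float
    stock: str
    deficit: float  # magnitude of the negative excursion that was clamped


@dataclass
class Trajectory:
    """Recorded run: stock values at each time point, realized flow rates per step."""

    times_months: np.ndarray
    times_years: np.ndarray
    stocks: dict[str, np.ndarray]  # length n_steps + 1
    flows: dict[str, np.ndarray]  # length n_steps (rate over [t, t+dt))
    clamp_events: list[ClampEvent] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"year": self.times_years})
        for name, series in self.stocks.items():
            frame[name] = series
        return frame


def evaluate_rates(
    state: Mapping[str, float], flows: Sequence[Flow], t_months: float
) -> dict[str, float]:
    """Evaluate every flow at the current state, aborting on non-finite rates."""
    rates: dict[str, float] = {}
    for f in flows:
        r = float(f.rate(state, t_months))
        if not math.isfinite(r):
            raise EngineError(f"flow {f.name!r} produced non-finite rate {r} at t={t_months}")
        rates[f.name] = r
    return rates


def euler_step(
    state: Mapping[str, float],
    rates: Mapping[str, float],
    flows: Sequence[Flow],
    dt_months: float,
    t_months: float = 0.0,
    unclamped: frozenset[str] = frozenset(),
) -> tuple[dict[str, float], list[ClampEvent]]:
    """Advance all stocks by one forward-Euler step.

    Each stock receives ``dt * (sum of inflows - sum of outflows)``; results
    are clamped at zero and clamp events are returned (and logged).  Before
    clamping the update is conservative: the total across all stocks changes
    only by flows whose source or sink is external.
    """
    if not dt_months > 0:
        raise EngineError("dt_months must be positive")
    net = dict.fromkeys(state, 0.0)
    for f in flows:
        r = rates[f.name]
        if not math.isfinite(r):
            raise EngineError(f"flow {f.name!r} has non-finite rate {r}")
        if f.source is not None:
            net[f.source] -= r
        if f.sink is not None:
            net[f.sink] += r
    new_state: dict[str, float] = {}
    clamps: list[ClampEvent] = []
    for name, value in state.items():
        updated = value + dt_months * net[name]
        if updated < 0.0 and name not in unclamped:
            clamps.append(ClampEvent(t_months, name, -updated))
            logger.warning(
                "stock %r clamped at zero at t=%.1f months (deficit %.3g)",
                name, t_months, -updated,
            )
            updated = 0.0
        new_state[name] = updated
    return new_state, clamps


def integrate(system: StockFlowSystem, clock: SimulationClock) -> Trajectory:
    """Forward-Euler trajectory of ``system`` over the full clock.

    Deterministic: identical inputs produce bit-identical outputs.
    """
    system.validate()
    n = clock.n_steps
    dt = clock.dt_months
    names = list(system.stocks)
    stock_series = {s: np.empty(n + 1) for s in names}
    flow_series = {f.name: np.empty(n) for f in system.flows}
    state = dict(system.stocks)
    for s in names:
        stock_series[s][0] = state[s]
    clamp_events: list[ClampEvent] = []
    for k in range(n):
        t = k * dt
        rates = evaluate_rates(state, system.flows, t)
        for fname, r in rates.items():
            flow_series[fname][k] = r
        state, clamps = euler_step(state, rates, system.flows, dt, t, system.unclamped)
        clamp_events.extend(clamps)
        for s in names:
            stock_series[s][k + 1] = state[s]
    return Trajectory(
        times_months=clock.times_months(),
        times_years=clock.times_years(),
        stocks=stock_series,
        flows=flow_series,
        clamp_events=clamp_events,
    )
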