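"""The type 2 diabetes patient journey as a stock-and-flow system.

Five population stocks trace the journey from health to disease and back:

    normoglycemic -> (un)diagnosed pre-diabetic -> type 2 diabetic
                  <-       recovery paths        <- "no medicine necessary"

Transitions are first-order: a stock ``S`` with a published (fraction,
average time) pair empties at ``S * fraction / time`` per year, i.e. the
published fraction of the stock transits over the published average
residence time.  Deaths are per-capita outflows at rate 1/(remaining
lifetime), with the remaining lifetime of each disease stock equal to the
healthy life expectancy (81.7 y) minus a stock-specific shortening
(10 y undiagnosed pre-diabetes, 8 y diagnosed, 9 y T2DM).  Demographic
replenishment (births, migration) enters only the normoglycemic stock and
is computed each step so the total simulated population tracks the
exogenous national population trend.

Pre-diabetes onset splits the normoglycemic stock into a rapid,
obesity-driven compartment and a background compartment, each with its own
(fraction, time) pair; new pre-diabetics are split instantaneously into
diagnosed (IFG/IGT) and undiagnosed inflows.  Cumulative deaths,
recoveries and demographic inflow are tracked in accounting stocks so that
population conservation can be audited exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .engine import EXTERNAL, Flow, SimulationClock, StockFlowSystem

__all__ = [
    "NORMO", "UNDIAG", "DIAG", "T2DM", "NOMED",
    "CUM_DEATHS", "CUM_RECOV", "CUM_INFLOW", "PERSON_STOCKS",
    "Transition", "JourneyParameters", "JourneyState",
    "transition_rate", "prediabetes_onset", "diagnosis_split", "death_rate",
    "journey_derivatives", "initialize_state", "build_journey_system",
    "DEFAULT_TRANSITIONS",
]

# -- stock names -------------------------------------------------------------
NORMO = "normoglycemic"
UNDIAG = "undiagnosed_prediabetic"
DIAG = "diagnosed_prediabetic"
T2DM = "t2dm"
NOMED = "no_medicine_necessary"
#: accounting stocks (not persons currently alive in the journey)
CUM_DEATHS = "cumulative_deaths"
CUM_RECOV = "cumulative_recoveries"
CUM_INFLOW = "cumulative_demographic_inflow"

PERSON_STOCKS = (NORMO, UNDIAG, DIAG, T2DM, NOMED)

#: compartment labels for the onset split of the normoglycemic stock
NORMO_BACKGROUND = "normoglycemic_background"
NORMO_RAPID = "normoglycemic_rapid"
PREDIABETES_POOL = "prediabetes_pool"  # instantaneous junction, not a stock


class ConfigurationError(ValueError):
    """Raised when journey parameters violate their invariants."""


@dataclass(frozen=True)
class Transition:
    """A published (fraction, average time) transition pair."""

    fraction: float
    avg_time_years: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigurationError(f"fraction {self.fraction} outside [0, 1]")
        if not self.avg_time_years > 0:
            raise ConfigurationError(f"avg_time {self.avg_time_years} must be > 0")

    @property
    def yearly_rate(self) -> float:
        return self.fraction / self.avg_time_years


#: Published transition table: (source, destination) -> (fraction, years).
#: The two relapse rows parameterize the "no medicine necessary" stock for
#: lifestyle reversal and bariatric surgery respectively.
DEFAULT_TRANSITIONS: dict[tuple[str, str], Transition] = {
    (NORMO_BACKGROUND, PREDIABETES_POOL): Transition(0.01, 2.0),
    (NORMO_RAPID, PREDIABETES_POOL): Transition(0.33, 3.0),
    (DIAG, T2DM): Transition(0.70, 4.0),
    (UNDIAG, T2DM): Transition(0.90, 7.0),
    (DIAG, NORMO): Transition(0.30, 2.0),
    (UNDIAG, NORMO): Transition(0.10, 4.0),
    (T2DM, NORMO): Transition(0.01, 3.0),
    (NOMED, T2DM): Transition(0.65, 2.0),
}
#: Bariatric-surgery relapse variant of the (no-medicine -> T2DM) row.
BARIATRIC_RELAPSE = Transition(0.05, 10.0)

#: Alternate recovery parameterization in which the diagnosed and
#: undiagnosed pre-diabetes recovery fractions are 10% and 5% (the values
#: quoted alongside the motivation discussion); the transition-table values
#: (30% / 10%) are the default.
ALTERNATE_RECOVERY_TRANSITIONS = {
    (DIAG, NORMO): Transition(0.10, 2.0),
    (UNDIAG, NORMO): Transition(0.05, 4.0),
}

#: Default share of the normoglycemic stock on the rapid, obesity-driven
#: onset pathway.  Calibrated placeholder: the published overweight share
#: (0.51) combined with the published (3 y, 0.33) pair overstates national
#: pre-diabetes incidence by more than an order of magnitude relative to the
#: historical T2DM counts the model must reproduce; this default was fitted
#: once against the 1990/2011/2018 count anchors (see docs/methods.md).
#: Set it to the literal overweight share to recover the face-value variant.
DEFAULT_RAPID_ONSET_SHARE = 0.002


def _as_series(value: float | Mapping[int, float]) -> dict[int, float]:
    if isinstance(value, Mapping):
        return {int(y): float(v) for y, v in value.items()}
    return {0: float(value)}


def _interp_series(series: Mapping[int, float], year: float) -> float:
    """Piecewise-linear interpolation with flat extrapolation."""
    years = sorted(series)
    if len(years) == 1:
        return series[years[0]]
    return float(np.interp(year, years, [series[y] for y in years]))


@dataclass
class JourneyParameters:
    """Everything that parameterizes the patient-journey stock structure.

    Times are years in the configuration (converted to months at the rate
    level); fractions are dimensionless.  Exogenous series are mappings
    year -> value, linearly interpolated and flat-extrapolated; a bare float
    is treated as a constant series.
    """

    transitions: dict[tuple[str, str], Transition] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITIONS)
    )
    ifg_fraction: float = 0.25
    igt_fraction: float = 0.25
    healthy_life_expectancy: float = 81.7
    lifespan_shortening: dict[str, float] = field(
        default_factory=lambda: {UNDIAG: 10.0, DIAG: 8.0, T2DM: 9.0}
    )
    t2dm_fraction_of_dm: float = 0.9
    #: (year, T2DM persons) pair anchoring the initial T2DM stock
    anchor_year: int = 1990
    anchor_t2dm: float = 144_000.0  # 160,000 DM patients x 0.9
    population_trend: Mapping[int, float] = field(default_factory=dict)
    overweight_fraction: float | Mapping[int, float] = 0.51
    obese_fraction: float | Mapping[int, float] = 0.15
    rapid_onset_share: float | Mapping[int, float] = DEFAULT_RAPID_ONSET_SHARE
    #: scale on the steady-state-consistent pre-diabetic seeds at t = 0
    #: (0 = empty disease pipeline at the start year, 1 = full steady state);
    #: the default starts the pipeline empty, matching the low historical
    #: prevalence at the 1990 anchor (see docs/methods.md)
    initial_prediabetic_scale: float = 0.0
    #: relapse behaviour of the shared "no medicine necessary" stock; the
    #: scenario layer overrides this with the active program's values
    relapse: Transition = field(default_factory=lambda: Transition(0.65, 2.0))

    def __post_init__(self) -> None:
        self.population_trend = _as_series(self.population_trend) if self.population_trend else {}
        for frac, name in (
            (self.ifg_fraction, "ifg_fraction"),
            (self.igt_fraction, "igt_fraction"),
            (self.t2dm_fraction_of_dm, "t2dm_fraction_of_dm"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} = {frac} outside [0, 1]")
        if self.ifg_fraction + self.igt_fraction > 1.0 + 1e-12:
            raise ConfigurationError("ifg_fraction + igt_fraction exceeds 1")
        for stock, short in self.lifespan_shortening.items():
            if short >= self.healthy_life_expectancy:
                raise ConfigurationError(
                    f"lifespan shortening for {stock} ({short} y) is not "
                    f"smaller than the healthy life expectancy"
                )
        if self.population_trend:
            for year, pop in self.population_trend.items():
                if pop <= 0:
                    raise ConfigurationError(f"population trend at {year} is {pop}")

    # -- exogenous lookups ---------------------------------------------------
    def population(self, year: float) -> float:
        if not self.population_trend:
            raise ConfigurationError("no population trend configured")
        return _interp_series(self.population_trend, year)

    def overweight_at(self, year: float) -> float:
        return _interp_series(_as_series(self.overweight_fraction), year)

    def rapid_share_at(self, year: float) -> float:
        return _interp_series(_as_series(self.rapid_onset_share), year)

    def remaining_life(self, stock: str) -> float:
        """Residence time (years) of the mortality outflow of ``stock``."""
        return self.healthy_life_expectancy - self.lifespan_shortening.get(stock, 0.0)


@dataclass
class JourneyState:
    """The five population stocks plus cumulative accounting at one time."""

    normoglycemic: float
    undiagnosed_prediabetic: float = 0.0
    diagnosed_prediabetic: float = 0.0
    t2dm: float = 0.0
    no_medicine_necessary: float = 0.0
    cumulative_deaths: float = 0.0
    cumulative_recoveries: float = 0.0
    cumulative_demographic_inflow: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if name != CUM_INFLOW and value < 0:
                raise ConfigurationError(f"stock {name} initialized to {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            NORMO: self.normoglycemic,
            UNDIAG: self.undiagnosed_prediabetic,
            DIAG: self.diagnosed_prediabetic,
            T2DM: self.t2dm,
            NOMED: self.no_medicine_necessary,
            CUM_DEATHS: self.cumulative_deaths,
            CUM_RECOV: self.cumulative_recoveries,
            CUM_INFLOW: self.cumulative_demographic_inflow,
        }

    @property
    def total_persons(self) -> float:
        return (
            self.normoglycemic + self.undiagnosed_prediabetic
            + self.diagnosed_prediabetic + self.t2dm + self.no_medicine_necessary
        )


# -- elementary operations ---------------------------------------------------

def transition_rate(stock_value: float, fraction: float, avg_time_years: float) -> float:
    """First-order transfer rate in persons per month.

    ``stock * fraction / (avg_time * 12)``: the published fraction of the
    stock transits over the published average time.
    """
    if avg_time_years <= 0:
        raise ConfigurationError(f"avg_time {avg_time_years} must be positive")
    if stock_value < 0:
        raise ConfigurationError(f"stock value {stock_value} is negative")
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError(f"fraction {fraction} outside [0, 1]")
    return stock_value * fraction / (avg_time_years * 12.0)


def prediabetes_onset(
    normoglycemic: float,
    overweight_fraction: float,
    params: JourneyParameters,
) -> float:
    """Total pre-diabetes onset rate (persons/month).

    The normoglycemic stock is split into a high-risk compartment of the
    given share and a background compartment; each empties into the
    pre-diabetes pool with its own (fraction, time) pair.
    """
    if not 0.0 <= overweight_fraction <= 1.0:
        raise ConfigurationError(
            f"overweight fraction {overweight_fraction} outside [0, 1]"
        )
    rapid = params.transitions[(NORMO_RAPID, PREDIABETES_POOL)]
    background = params.transitions[(NORMO_BACKGROUND, PREDIABETES_POOL)]
    at_risk = normoglycemic * overweight_fraction
    rest = normoglycemic - at_risk
    return (
        transition_rate(at_risk, rapid.fraction, rapid.avg_time_years)
        + transition_rate(rest, background.fraction, background.avg_time_years)
    )


def diagnosis_split(
    onset_rate: float, ifg_fraction: float, igt_fraction: float
) -> tuple[float, float]:
    """Split the onset flow into (diagnosed, undiagnosed) inflows.

    The diagnosed share is the combined IFG + IGT incidence fraction; the
    two outputs sum to the onset rate exactly.
    """
    diagnosed_share = ifg_fraction + igt_fraction
    if diagnosed_share > 1.0 + 1e-12:
        raise ConfigurationError(
            f"IFG + IGT fractions sum to {diagnosed_share} > 1"
        )
    diagnosed = onset_rate * diagnosed_share
    return diagnosed, onset_rate - diagnosed


def death_rate(stock_value: float, remaining_life_years: float) -> float:
    """Per-capita mortality outflow, persons per month.

    Exponential residence-time approximation of "leaving the stock on
    reaching the life expectancy of that health state".
    """
    if remaining_life_years <= 0:
        raise ConfigurationError("remaining life must be positive")
    if stock_value < 0:
        raise ConfigurationError(f"stock value {stock_value} is negative")
    return stock_value / (remaining_life_years * 12.0)


# -- assembled model ---------------------------------------------------------

def initialize_state(params: JourneyParameters, clock: SimulationClock) -> JourneyState:
    """Initial stocks at January of the clock's start year.

    The T2DM stock is pinned to the prevalence anchor; the pre-diabetic
    stocks are seeded at their steady-state shares of the normoglycemic
    stock (so the early trajectory is free of filling transients); the
    normoglycemic stock takes up the remainder of the population trend,
    which therefore equals the total of all stocks at t = 0.
    """
    year = clock.start_year
    population = params.population(year)
    if params.anchor_year != year:
        # scale the anchor through the prevalence fraction it implies
        anchor_frac = params.anchor_t2dm / params.population(params.anchor_year)
        t2dm0 = population * anchor_frac
    else:
        t2dm0 = params.anchor_t2dm
    if t2dm0 > population:
        raise ConfigurationError("anchor T2DM stock exceeds the population trend")

    # steady-state-consistent pre-diabetic seeds: inflow share / outflow rate
    w = params.rapid_share_at(year)
    rapid = params.transitions[(NORMO_RAPID, PREDIABETES_POOL)]
    background = params.transitions[(NORMO_BACKGROUND, PREDIABETES_POOL)]
    onset_per_normo = w * rapid.yearly_rate + (1.0 - w) * background.yearly_rate
    diagnosed_share = params.ifg_fraction + params.igt_fraction
    out_u = (
        params.transitions[(UNDIAG, T2DM)].yearly_rate
        + params.transitions[(UNDIAG, NORMO)].yearly_rate
        + 1.0 / params.remaining_life(UNDIAG)
    )
    out_d = (
        params.transitions[(DIAG, T2DM)].yearly_rate
        + params.transitions[(DIAG, NORMO)].yearly_rate
        + 1.0 / params.remaining_life(DIAG)
    )
    scale = params.initial_prediabetic_scale
    if not 0.0 <= scale <= 1.0:
        raise ConfigurationError("initial_prediabetic_scale outside [0, 1]")
    u_share = scale * onset_per_normo * (1.0 - diagnosed_share) / out_u
    d_share = scale * onset_per_normo * diagnosed_share / out_d
    normo0 = (population - t2dm0) / (1.0 + u_share + d_share)
    if normo0 < 0:
        raise ConfigurationError("initial normoglycemic stock is negative")
    return JourneyState(
        normoglycemic=normo0,
        undiagnosed_prediabetic=u_share * normo0,
        diagnosed_prediabetic=d_share * normo0,
        t2dm=t2dm0,
    )


def _build_flows(
    params: JourneyParameters,
    clock: SimulationClock,
    program_flows: Sequence[Flow] = (),
) -> list[Flow]:
    """All journey flows as engine Flow objects (program flows appended)."""
    tr = params.transitions
    start_year = clock.start_year
    dt = clock.dt_months

    def year_at(t: float) -> float:
        return start_year + t / 12.0

    def onset(state: Mapping[str, float], t: float) -> float:
        return prediabetes_onset(state[NORMO], params.rapid_share_at(year_at(t)), params)

    def onset_diagnosed(state: Mapping[str, float], t: float) -> float:
        return diagnosis_split(onset(state, t), params.ifg_fraction, params.igt_fraction)[0]

    def onset_undiagnosed(state: Mapping[str, float], t: float) -> float:
        return diagnosis_split(onset(state, t), params.ifg_fraction, params.igt_fraction)[1]

    def first_order(source: str, dest: str):
        pair = tr[(source, dest)]
        return lambda state, t: transition_rate(
            state[source], pair.fraction, pair.avg_time_years
        )

    def mortality(stock: str):
        life = params.remaining_life(stock)
        return lambda state, t: death_rate(state[stock], life)

    def relapse(state: Mapping[str, float], t: float) -> float:
        return transition_rate(
            state[NOMED], params.relapse.fraction, params.relapse.avg_time_years
        )

    def sustained_recovery(state: Mapping[str, float], t: float) -> float:
        return transition_rate(
            state[NOMED], 1.0 - params.relapse.fraction, params.relapse.avg_time_years
        )

    def replenishment(state: Mapping[str, float], t: float) -> float:
        total = sum(state[s] for s in PERSON_STOCKS)
        return (params.population(year_at(t)) - total) / dt

    flows: list[Flow] = [
        Flow("prediabetes_onset_diagnosed", NORMO, DIAG, onset_diagnosed),
        Flow("prediabetes_onset_undiagnosed", NORMO, UNDIAG, onset_undiagnosed),
        Flow("diagnosed_to_t2dm", DIAG, T2DM, first_order(DIAG, T2DM)),
        Flow("undiagnosed_to_t2dm", UNDIAG, T2DM, first_order(UNDIAG, T2DM)),
        Flow("diagnosed_recovery", DIAG, NORMO, first_order(DIAG, NORMO)),
        Flow("undiagnosed_recovery", UNDIAG, NORMO, first_order(UNDIAG, NORMO)),
        Flow("t2dm_baseline_recovery", T2DM, NORMO, first_order(T2DM, NORMO)),
        Flow("relapse", NOMED, T2DM, relapse),
        Flow("sustained_recovery", NOMED, NORMO, sustained_recovery),
        Flow("deaths_normoglycemic", NORMO, CUM_DEATHS, mortality(NORMO)),
        Flow("deaths_undiagnosed", UNDIAG, CUM_DEATHS, mortality(UNDIAG)),
        Flow("deaths_diagnosed", DIAG, CUM_DEATHS, mortality(DIAG)),
        Flow("deaths_t2dm", T2DM, CUM_DEATHS, mortality(T2DM)),
        Flow("demographic_replenishment", EXTERNAL, NORMO, replenishment),
        Flow("demographic_inflow_tracker", EXTERNAL, CUM_INFLOW, replenishment),
    ]
    flows.extend(program_flows)

    recovery_flow_names = [
        f.name
        for f in flows
        if f.sink == NORMO and f.source in (UNDIAG, DIAG, T2DM, NOMED)
    ]
    flow_by_name = {f.name: f for f in flows}

    def recoveries(state: Mapping[str, float], t: float) -> float:
        return sum(flow_by_name[n].rate(state, t) for n in recovery_flow_names)

    flows.append(Flow("recovery_tracker", EXTERNAL, CUM_RECOV, recoveries))
    return flows


def journey_derivatives(
    state: Mapping[str, float] | JourneyState,
    params: JourneyParameters,
    program_flows: Sequence[Flow] = (),
    t_months: float = 0.0,
    clock: SimulationClock | None = None,
) -> dict[str, float]:
    """Evaluate every named flow rate (persons/month) at one state and time."""
    if isinstance(state, JourneyState):
        state = state.as_dict()
    clock = clock or SimulationClock()
    flows = _build_flows(params, clock, program_flows)
    return {f.name: float(f.rate(state, t_months)) for f in flows}


def build_journey_system(
    params: JourneyParameters,
    clock: SimulationClock,
    program_flows: Sequence[Flow] = (),
    initial: JourneyState | None = None,
) -> StockFlowSystem:
    """Assemble the full journey as an integrable StockFlowSystem."""
    state = initial if initial is not None else initialize_state(params, clock)
    system = StockFlowSystem(
        stocks=state.as_dict(),
        flows=_build_flows(params, clock, program_flows),
        auxiliaries={"params": params},
        unclamped=frozenset({CUM_INFLOW}),
    )
    system.validate()
    return system


def with_alternate_recovery(params: JourneyParameters) -> JourneyParameters:
    """Variant with the 10% / 5% pre-diabetes recovery fractions."""
    transitions = dict(params.transitions)
    transitions.update(ALTERNATE_RECOVERY_TRANSITIONS)
    return replace(params, transitions=transitions)
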