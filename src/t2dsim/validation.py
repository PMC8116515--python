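"""Model validation procedures: extreme-condition tests, one-at-a-time
behavior sensitivity analysis, and behavior reproduction against the
historical reference anchors.

All three are pure reporting: they build their own parameter copies, never
mutate the configuration they are given, and are bit-for-bit reproducible.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .costs import CostParameters, annual_cost
from .engine import SimulationClock, integrate
from .journey import (
    DIAG, NOMED, PERSON_STOCKS, T2DM, UNDIAG,
    NORMO_BACKGROUND, NORMO_RAPID, PREDIABETES_POOL,
    ConfigurationError, JourneyParameters, JourneyState, Transition,
    build_journey_system,
)
from .scenarios import Scenario, ScenarioResult, run_scenario

__all__ = [
    "AnchorPoint", "ReferenceAnchors", "SensitivityReport", "FitReport",
    "extreme_condition_test", "sensitivity_analysis", "behavior_reproduction",
    "DEFAULT_ANCHORS",
]


@dataclass(frozen=True)
class AnchorPoint:
    year: int
    kind: str  # "dm_count" or "t2dm_fraction"
    value: float


@dataclass(frozen=True)
class ReferenceAnchors:
    """Historical reference points printed in national statistics."""

    points: tuple[AnchorPoint, ...]

    def __post_init__(self) -> None:
        for p in self.points:
            if p.kind not in ("dm_count", "t2dm_fraction"):
                raise ConfigurationError(f"unknown anchor kind {p.kind!r}")
            if p.kind == "t2dm_fraction" and not 0.0 <= p.value <= 1.0:
                raise ConfigurationError(f"fraction anchor {p.value} outside [0, 1]")


#: Text-printed CBS reference points: total-DM counts and registered T2DM
#: population fractions.  Note the two kinds are on different bases (the
#: count series includes estimated undiagnosed patients) and are mutually
#: inconsistent around 2018/2019; see docs/methods.md.
DEFAULT_ANCHORS = ReferenceAnchors((
    AnchorPoint(1990, "dm_count", 160_000.0),
    AnchorPoint(2011, "dm_count", 830_000.0),
    AnchorPoint(2018, "dm_count", 1_200_000.0),
    AnchorPoint(2014, "t2dm_fraction", 0.037),
    AnchorPoint(2019, "t2dm_fraction", 0.040),
))


# -- extreme condition test ---------------------------------------------------

@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str


@dataclass
class ExtremeConditionReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name: str, passed: bool, detail: str) -> None:
        self.checks.append(CheckResult(name, bool(passed), detail))


def extreme_condition_test(
    journey_params: JourneyParameters,
    cost_params: CostParameters,
    clock: SimulationClock | None = None,
) -> ExtremeConditionReport:
    """Run the documented extremes and report each rationality assertion.

    Extreme 1 (empty system): every disease stock zero and onset disabled
    must yield exactly zero T2DM-attributable cost in every year.
    Extreme 2 (100 million patients): costs must scale into the billions,
    stay proportional to the stock, and no stock may go negative or
    non-finite.
    """
    clock = clock or SimulationClock()
    report = ExtremeConditionReport()

    # extreme 1: zero disease stocks, onset disabled
    params0 = replace(
        journey_params,
        transitions={
            **journey_params.transitions,
            (NORMO_BACKGROUND, PREDIABETES_POOL): Transition(0.0, 2.0),
            (NORMO_RAPID, PREDIABETES_POOL): Transition(0.0, 3.0),
        },
        anchor_year=clock.start_year,
        anchor_t2dm=0.0,
    )
    initial = JourneyState(normoglycemic=params0.population(clock.start_year))
    result = run_scenario(
        Scenario("extreme_zero", []), params0, cost_params, clock, initial=initial
    )
    max_cost = float(result.annual["cost_total"].abs().max())
    report.add(
        "zero patients give zero cost", max_cost == 0.0,
        f"max |annual total cost| = {max_cost:.3g} EUR",
    )
    disease_max = float(
        result.annual[[UNDIAG, DIAG, T2DM, NOMED]].to_numpy().max()
    )
    report.add(
        "disease stocks stay empty", disease_max == 0.0,
        f"max disease stock = {disease_max:.3g} persons",
    )

    # extreme 2: 100 million patients
    big = 100e6
    state_big = JourneyState(normoglycemic=0.0, t2dm=big)
    cost_big = annual_cost(state_big, cost_params, (), clock.start_year).total
    cost_half = annual_cost(
        JourneyState(normoglycemic=0.0, t2dm=big / 2), cost_params, (),
        clock.start_year,
    ).total
    report.add(
        "100 M patients cost billions", cost_big > 1e9,
        f"annual cost at 100 M T2DM patients = {cost_big:.4g} EUR",
    )
    report.add(
        "costs scale proportionally with the stock",
        math.isclose(cost_big, 2 * cost_half, rel_tol=1e-9),
        f"cost(100 M) / cost(50 M) = {cost_big / cost_half:.12g}",
    )
    params_big = replace(journey_params, anchor_year=clock.start_year, anchor_t2dm=0.0)
    initial_big = JourneyState(normoglycemic=big)
    traj = integrate(
        build_journey_system(params_big, clock, initial=initial_big), clock
    )
    finite = all(np.all(np.isfinite(v)) for v in traj.stocks.values())
    nonneg = all(np.all(traj.stocks[s] >= 0) for s in PERSON_STOCKS)
    report.add(
        "100 M normoglycemic run stays finite", finite,
        "all stock trajectories finite",
    )
    report.add(
        "no population stock goes negative", nonneg,
        "all person-stock trajectories >= 0",
    )
    return report


# -- sensitivity analysis -----------------------------------------------------

#: dotted-path addressing of perturbable scalar parameters
def _get_param(params: JourneyParameters, name: str) -> float:
    parts = name.split(".")
    if parts[0] == "transitions":
        key = (parts[1], parts[2])
        tr = params.transitions[key]
        return getattr(tr, parts[3])
    value = getattr(params, parts[0])
    if len(parts) == 1:
        if isinstance(value, Mapping):
            raise ConfigurationError(f"parameter {name!r} is a series, not a scalar")
        return float(value)
    return float(value[parts[1]])


def _set_param(params: JourneyParameters, name: str, value: float) -> JourneyParameters:
    out = copy.deepcopy(params)
    parts = name.split(".")
    if parts[0] == "transitions":
        key = (parts[1], parts[2])
        tr = out.transitions[key]
        out.transitions[key] = Transition(
            fraction=value if parts[3] == "fraction" else tr.fraction,
            avg_time_years=value if parts[3] == "avg_time_years" else tr.avg_time_years,
        )
        return out
    if len(parts) == 1:
        setattr(out, parts[0], value)
        return out
    getattr(out, parts[0])[parts[1]] = value
    return out


@dataclass
class SensitivityReport:
    """One-at-a-time elasticities of every population stock.

    ``elasticities[parameter][stock]`` holds the central-difference
    elasticity (relative output change / relative parameter change) at the
    report year; ``outputs`` holds the perturbed raw stock values.
    """

    output_year: int
    perturbation: float
    baseline: dict[str, float]
    elasticities: dict[str, dict[str, float]] = field(default_factory=dict)
    outputs: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)

    def ranked(self, stock: str) -> list[tuple[str, float]]:
        """Parameters sorted by |elasticity| on ``stock``, largest first."""
        pairs = [(p, e[stock]) for p, e in self.elasticities.items()]
        return sorted(pairs, key=lambda kv: abs(kv[1]), reverse=True)


def sensitivity_analysis(
    journey_params: JourneyParameters,
    cost_params: CostParameters,
    parameters: Sequence[str],
    perturbation: float = 0.10,
    output_year: int = 2035,
    clock: SimulationClock | None = None,
    scenario: Scenario | None = None,
) -> SensitivityReport:
    """Perturb each named parameter by +/- ``perturbation`` (relative) and
    report per-stock elasticities at ``output_year``.  Deterministic."""
    if perturbation <= 0:
        raise ConfigurationError("perturbation must be positive")
    clock = clock or SimulationClock()
    scenario = scenario or Scenario("sensitivity_baseline", [])

    def stocks_at(params: JourneyParameters) -> dict[str, float]:
        result = run_scenario(scenario, params, cost_params, clock)
        row = result.year_row(output_year)
        return {s: float(row[s]) for s in PERSON_STOCKS}

    baseline = stocks_at(journey_params)
    report = SensitivityReport(
        output_year=output_year, perturbation=perturbation, baseline=baseline
    )
    for name in parameters:
        base_value = _get_param(journey_params, name)  # raises on unknown name
        if base_value == 0.0:
            raise ConfigurationError(
                f"cannot perturb {name!r}: baseline value is zero"
            )
        up = stocks_at(_set_param(journey_params, name, base_value * (1 + perturbation)))
        down = stocks_at(_set_param(journey_params, name, base_value * (1 - perturbation)))
        elastic = {}
        for s in PERSON_STOCKS:
            if baseline[s] > 0:
                elastic[s] = (up[s] - down[s]) / baseline[s] / (2 * perturbation)
            else:
                elastic[s] = 0.0 if up[s] == down[s] else math.inf
        report.elasticities[name] = elastic
        report.outputs[name] = {"up": up, "down": down}
    return report


# -- behavior reproduction ----------------------------------------------------

@dataclass
class AnchorFit:
    anchor: AnchorPoint
    simulated: float
    relative_error: float


@dataclass
class FitReport:
    """Per-anchor relative errors of a run against the reference anchors."""

    tolerance: float
    fits: list[AnchorFit] = field(default_factory=list)

    @property
    def mape(self) -> float:
        return float(np.mean([abs(f.relative_error) for f in self.fits]))

    @property
    def passed(self) -> bool:
        return all(abs(f.relative_error) <= self.tolerance for f in self.fits)


def behavior_reproduction(
    result: ScenarioResult,
    anchors: ReferenceAnchors = DEFAULT_ANCHORS,
    journey_params: JourneyParameters | None = None,
    tolerance: float = 0.20,
) -> FitReport:
    """Compare a run against the reference anchors.

    Count anchors tally the whole diabetes population, so the simulated
    T2DM stock is divided by the T2DM share of DM (9 out of 10) before
    comparison; fraction anchors are compared against simulated T2DM over
    the population trend.  Anchors are matched against the opening
    (1 January) state of their year, the convention under which the start
    year's anchor coincides with the initial condition it defines.
    """
    if journey_params is None:
        raise ConfigurationError("journey_params required to resolve anchor bases")
    report = FitReport(tolerance=tolerance)
    for anchor in anchors.points:
        if not result.clock.start_year <= anchor.year <= result.clock.end_year:
            raise ConfigurationError(
                f"anchor year {anchor.year} outside simulated horizon"
            )
        t2dm = float(
            result.trajectory.stocks[T2DM][result.clock.year_start_index(anchor.year)]
        )
        if anchor.kind == "dm_count":
            simulated = t2dm / journey_params.t2dm_fraction_of_dm
        else:
            simulated = t2dm / journey_params.population(anchor.year)
        rel = (simulated - anchor.value) / anchor.value
        report.fits.append(AnchorFit(anchor, simulated, rel))
    return report
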