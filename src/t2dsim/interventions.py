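"""Lifestyle-program policy levers.

A program recruits from an eligible stock (T2DM patients, or diagnosed
pre-diabetics for prevention programs), moves the successful share of
recruits onto a recovery path, and prices each recruit at a multiple of the
standard program cost.  Recruitment is capacity-limited via MIN(indicated,
potential): the indicated rate is the recruited fraction of the eligible
stock, the potential rate is the annual treatment capacity.  Successful
T2DM participants enter the "no medicine necessary" stock, from which a
program-specific fraction relapses back to T2DM over a characteristic time
(65% over 2 years for lifestyle reversal, 5% over 10 years after bariatric
surgery); prevention-program successes return directly to the
normoglycemic stock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .engine import Flow, SimulationClock
from .journey import (
    DIAG, NOMED, NORMO, T2DM,
    BARIATRIC_RELAPSE, ConfigurationError, JourneyParameters, Transition,
    transition_rate,
)

__all__ = [
    "ProgramSpec", "recruitment_rate", "program_recovery_flow", "relapse_flow",
    "current_recruited_fraction", "build_program_flows", "resolve_relapse",
]

#: default relapse behaviour by program target
_RELAPSE_DEFAULTS = {
    "t2dm": Transition(0.65, 2.0),
    "prediabetes": Transition(0.65, 2.0),
    "bariatric": BARIATRIC_RELAPSE,
}


@dataclass
class ProgramSpec:
    """One intervention program's policy levers.

    ``fraction_recruited`` is the recruited fraction of the eligible stock
    per year at activation; when ``fraction_recruited_final`` differs, the
    fraction ramps linearly from the former to the latter over
    ``ramp_years`` after activation (step activation when ``ramp_years`` is
    zero).  ``capacity`` caps treated patients per year (unlimited when
    ``None``).  ``cost_multiplier`` scales the standard per-participant
    program cost.
    """

    name: str
    target: str = "t2dm"  # one of {"t2dm", "prediabetes", "bariatric"}
    active: bool = True
    activation_year: int = 2020
    fraction_recruited: float = 0.0
    fraction_recruited_final: float | None = None
    ramp_years: float = 0.0
    success_rate: float = 0.0
    cost_multiplier: float = 1.0
    capacity: float | None = None
    relapse_fraction: float | None = None
    relapse_time: float | None = None

    def __post_init__(self) -> None:
        if self.target not in _RELAPSE_DEFAULTS:
            raise ConfigurationError(
                f"unknown program target {self.target!r}; expected one of "
                f"{sorted(_RELAPSE_DEFAULTS)}"
            )
        default = _RELAPSE_DEFAULTS[self.target]
        if self.relapse_fraction is None:
            self.relapse_fraction = default.fraction
        if self.relapse_time is None:
            self.relapse_time = default.avg_time_years
        for value, name in (
            (self.fraction_recruited, "fraction_recruited"),
            (self.success_rate, "success_rate"),
            (self.relapse_fraction, "relapse_fraction"),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} = {value} outside [0, 1]")
        if self.fraction_recruited_final is not None and not (
            0.0 <= self.fraction_recruited_final <= 1.0
        ):
            raise ConfigurationError("fraction_recruited_final outside [0, 1]")
        if self.cost_multiplier <= 0:
            raise ConfigurationError("cost_multiplier must be positive")
        if self.ramp_years < 0:
            raise ConfigurationError("ramp_years must be >= 0")
        if self.capacity is not None and self.capacity < 0:
            raise ConfigurationError("capacity must be >= 0")

    @property
    def relapse(self) -> Transition:
        return Transition(self.relapse_fraction, self.relapse_time)

    @property
    def eligible_stock(self) -> str:
        return DIAG if self.target == "prediabetes" else T2DM


def current_recruited_fraction(spec: ProgramSpec, t_months: float, clock: SimulationClock) -> float:
    """Recruited fraction per year at time ``t``: 0 before activation, then a
    linear ramp from the initial to the final fraction over ``ramp_years``."""
    years_since = (clock.start_year + t_months / 12.0) - spec.activation_year
    if not spec.active or years_since < 0:
        return 0.0
    final = (
        spec.fraction_recruited
        if spec.fraction_recruited_final is None
        else spec.fraction_recruited_final
    )
    if spec.ramp_years <= 0:
        return final
    progress = min(1.0, years_since / spec.ramp_years)
    return spec.fraction_recruited + (final - spec.fraction_recruited) * progress


def recruitment_rate(
    eligible_stock: float,
    spec: ProgramSpec,
    t_months: float,
    clock: SimulationClock,
) -> float:
    """Persons recruited per month: MIN(indicated, potential), where the
    indicated rate applies the current recruited fraction to the eligible
    stock and the potential rate is the annual capacity.  Never exceeds
    what the eligible stock can supply in one time step."""
    fraction = current_recruited_fraction(spec, t_months, clock)
    if fraction == 0.0 or eligible_stock <= 0.0:
        return 0.0
    indicated = eligible_stock * fraction / 12.0
    if spec.capacity is not None:
        indicated = min(indicated, spec.capacity / 12.0)
    return min(indicated, eligible_stock / clock.dt_months)


def program_recovery_flow(recruited: float, success_rate: float) -> float:
    """Successful recoveries per month; the remainder stays in its stock."""
    if not 0.0 <= success_rate <= 1.0:
        raise ConfigurationError(f"success_rate {success_rate} outside [0, 1]")
    return recruited * success_rate


def relapse_flow(no_medicine_stock: float, spec: ProgramSpec) -> float:
    """Relapse rate (persons/month) from "no medicine necessary" to T2DM."""
    return transition_rate(no_medicine_stock, spec.relapse_fraction, spec.relapse_time)


def resolve_relapse(programs: Sequence[ProgramSpec], params: JourneyParameters) -> Transition:
    """Relapse behaviour of the shared no-medicine stock for a scenario run.

    The active T2DM-target program's relapse parameters govern the stock;
    with no such program the lifestyle default from the transition table
    applies.  Two active T2DM programs with conflicting relapse behaviour
    are rejected (the model has a single reversal stock).
    """
    candidates = [
        p.relapse for p in programs if p.active and p.target in ("t2dm", "bariatric")
    ]
    if not candidates:
        return params.relapse
    if any(c != candidates[0] for c in candidates[1:]):
        raise ConfigurationError(
            "active T2DM programs disagree on relapse behaviour of the "
            "shared no-medicine stock"
        )
    return candidates[0]


def build_program_flows(
    programs: Sequence[ProgramSpec], clock: SimulationClock
) -> list[Flow]:
    """Engine flows implementing every active program's recovery channel."""
    flows: list[Flow] = []
    for spec in programs:
        if not spec.active:
            continue
        flows.extend(_flows_for(spec, clock))
    return flows


def _flows_for(spec: ProgramSpec, clock: SimulationClock) -> list[Flow]:
    stock = spec.eligible_stock
    sink = NORMO if spec.target == "prediabetes" else NOMED

    def recruit(state: Mapping[str, float], t: float) -> float:
        return recruitment_rate(state[stock], spec, t, clock)

    def recovery(state: Mapping[str, float], t: float) -> float:
        return program_recovery_flow(recruit(state, t), spec.success_rate)

    return [
        # bookkeeping flow (zero net transfer) so recruitment is recorded
        Flow(f"recruitment[{spec.name}]", stock, stock, recruit),
        Flow(f"program_recovery[{spec.name}]", stock, sink, recovery),
    ]
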