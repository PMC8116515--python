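"""Societal cost accounting for the T2DM patient journey.

Annual cost is a linear function of the population stocks: each component
is (relevant population count) x (per-patient unit cost) x (relevant
fraction), grouped by payer:

* Dutch authorities - statutory disability benefits (full/permanent IVA
  and partial WGA schemes under the WIA act), claimed by the disabled
  share of the employed T2DM population;
* employer - obligatory salary continuation for disabled employees plus
  productivity loss of the employed (pre)diabetic workforce;
* health insurer - ambulatory care, hospitalization, physiotherapy, tools
  and devices, GP care, medication (a standard/elderly blend, since
  insulin management differs in elderly bodies) and comorbidity care;
* DM management organizations - patient-association overhead;
* programs - recruits per year x standard program cost x the program's
  cost multiplier.

Unit costs published for the whole diabetes population are scaled to T2DM
by the 9-out-of-10 share.  All unit-cost defaults are calibrated
placeholders (the source parameterization is not public); they are chosen
at realistic Dutch magnitudes and scaled once so the default
no-intervention run totals ~13 billion euros per year by 2035.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from typing import Mapping, Sequence

import numpy as np

from .interventions import ProgramSpec
from .journey import (
    DIAG, T2DM, UNDIAG,
    ConfigurationError, JourneyState, _as_series, _interp_series,
)

__all__ = ["CostParameters", "CostBreakdown", "annual_cost", "cumulative_cost"]

#: insurer components published on a whole-DM basis (scaled by x0.9 to T2DM)
_INSURER_COMPONENTS = (
    "ambulatory_care", "hospitalization", "physiotherapy", "tools_devices",
    "gp_care", "comorbidity",
)


@dataclass
class CostParameters:
    """Per-patient annual unit costs (euros/person/year) and cost fractions.

    Every unit cost carries provenance ``calibrated-placeholder`` unless
    stated otherwise in the shipped configuration.
    """

    # authorities: benefit schemes, paid to the disabled share
    wia_iva_benefit: float = 13_000.0
    wga_benefit: float = 10_000.0
    # employer
    employer_salary_continuation: float = 6_600.0
    productivity_loss: float = 1_250.0
    # insurer (whole-DM basis unless noted)
    ambulatory_care: float = 800.0
    hospitalization: float = 1_400.0
    physiotherapy: float = 215.0
    tools_devices: float = 400.0
    gp_care: float = 275.0
    medication_standard: float = 875.0
    medication_elderly: float = 1_250.0
    comorbidity: float = 1_150.0
    # DM management organizations
    dm_management_orgs: float = 35.0
    # fractions
    disability_fraction: float = 0.05
    elderly_fraction: float | Mapping[int, float] = 0.5
    employment_fraction: float = 1.0  # "all patients are employed"
    dm_to_t2dm_fraction: float = 0.9
    # programs
    base_program_cost: float = 1_000.0
    bariatric_unit_cost_range: tuple[float, float] = (15_000.0, 20_000.0)
    #: which components the pre-diabetic stocks incur (at T2DM unit costs);
    #: GP care applies to the diagnosed stock only, productivity to both
    prediabetic_components: tuple[str, ...] = ("gp_care", "productivity_loss")

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            value = getattr(self, f.name)
            if isinstance(value, (int, float)) and f.name not in (
                "disability_fraction", "employment_fraction", "dm_to_t2dm_fraction",
            ):
                if value < 0:
                    raise ConfigurationError(f"unit cost {f.name} is negative")
        for name in ("disability_fraction", "employment_fraction", "dm_to_t2dm_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} = {value} outside [0, 1]")

    def elderly_at(self, year: float) -> float:
        return _interp_series(_as_series(self.elderly_fraction), year)

    def unit(self, component: str) -> float:
        try:
            value = getattr(self, component)
        except AttributeError:
            raise ConfigurationError(
                f"missing unit cost for component {component!r}"
            ) from None
        if value is None:
            raise ConfigurationError(f"missing unit cost for component {component!r}")
        return float(value)

    def medication_blend(self, year: float) -> float:
        e = self.elderly_at(year)
        return (1.0 - e) * self.medication_standard + e * self.medication_elderly


@dataclass(frozen=True)
class CostBreakdown:
    """Annual societal cost of one simulated year, decomposed by payer."""

    authorities: float
    insurer: float
    employer: float
    dm_management: float
    program: float

    @property
    def total(self) -> float:
        return (
            self.authorities + self.insurer + self.employer
            + self.dm_management + self.program
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "authorities": self.authorities,
            "insurer": self.insurer,
            "employer": self.employer,
            "dm_management": self.dm_management,
            "program": self.program,
            "total": self.total,
        }


def annual_cost(
    state: JourneyState | Mapping[str, float],
    params: CostParameters,
    programs: Sequence[tuple[ProgramSpec, float]] = (),
    year: int = 2020,
) -> CostBreakdown:
    """Cost breakdown for one year from end-of-year stocks.

    ``programs`` pairs each active program with its realized recruits per
    year.  Every component is linear in the stock that drives it.
    """
    stocks = state.as_dict() if isinstance(state, JourneyState) else dict(state)
    t2dm = stocks[T2DM]
    diagnosed_pre = stocks[DIAG]
    undiagnosed_pre = stocks[UNDIAG]
    dm_scale = params.dm_to_t2dm_fraction
    employed = t2dm * params.employment_fraction
    disabled = employed * params.disability_fraction

    authorities = disabled * (params.wia_iva_benefit + params.wga_benefit)

    employer = (
        disabled * params.employer_salary_continuation
        + employed * params.productivity_loss
    )

    insurer = t2dm * dm_scale * (
        sum(params.unit(c) for c in _INSURER_COMPONENTS)
        + params.medication_blend(year)
    )

    # pre-diabetic stocks: configurable slim component set
    for component in params.prediabetic_components:
        unit = params.unit(component)
        if component == "productivity_loss":
            employer += (
                (diagnosed_pre + undiagnosed_pre)
                * params.employment_fraction * unit
            )
        elif component == "gp_care":
            insurer += diagnosed_pre * unit
        else:
            insurer += (diagnosed_pre + undiagnosed_pre) * unit

    dm_management = t2dm * dm_scale * params.dm_management_orgs

    program_cost = 0.0
    for spec, recruits_per_year in programs:
        if spec.active and recruits_per_year > 0:
            program_cost += (
                recruits_per_year * params.base_program_cost * spec.cost_multiplier
            )

    return CostBreakdown(
        authorities=authorities,
        insurer=insurer,
        employer=employer,
        dm_management=dm_management,
        program=program_cost,
    )


def cumulative_cost(annual_totals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Running sum of annual totals (euros); non-decreasing for costs >= 0."""
    return np.cumsum(np.asarray(annual_totals, dtype=float))
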