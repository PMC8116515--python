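"""Policy scenarios: presets, end-to-end runs and comparisons.

Six preset experiments mirror the published what-if runs, all activated in
2020 on the 1990-2035 horizon:

======================  =====================================================
preset                  programs
======================  =====================================================
no_intervention         none (current policy)
policy1_bariatric       T2DM surgery: recruited 0.28, success 0.95,
                        cost multiplier 17, bariatric relapse (5% / 10 y)
policy2_reversediabetes2now
                        T2DM lifestyle: recruited 0.002 ramping to 0.30
                        over 10 years, success 0.28, multiplier 1
policy3                 T2DM 0.3 / 0.3 / x1.0
policy4                 T2DM 0.45 / 0.3 / x2.0 + pre-diabetes 0.3 / 0.3 / x1.0
policy5                 T2DM 0.6 / 0.5 / x3.0 + pre-diabetes 0.4 / 0.5 / x3.0
======================  =====================================================

The published narrative occasionally disagrees with the scenario table
(run 5 quotes a 45% success rate where the table lists recruited 0.45 and
success 0.3; run 6 quotes "pricing multiplied by 4" where the table lists
3.0).  The table is authoritative; the narrative variants ship as
additional presets with a ``_narrative`` suffix.  Scenario-run numbering
maps run1..run6 onto the presets in the order above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .costs import CostParameters, annual_cost, cumulative_cost
from .engine import SimulationClock, Trajectory, integrate
from .interventions import ProgramSpec, build_program_flows, resolve_relapse
from .journey import (
    T2DM, ConfigurationError, JourneyParameters, JourneyState,
    build_journey_system,
)

__all__ = [
    "Scenario", "ScenarioResult", "load_preset", "preset_names",
    "run_scenario", "compare", "scenario_to_dict", "scenario_from_dict",
    "dump_config", "load_config", "RUN_ALIASES",
]


@dataclass
class Scenario:
    """A named bundle of programs plus optional parameter overrides."""

    name: str
    programs: list[ProgramSpec] = field(default_factory=list)
    overrides: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.programs]
        if len(names) != len(set(names)):
            raise ConfigurationError(f"duplicate program names in scenario {self.name!r}")


@dataclass
class ScenarioResult:
    """Trajectories and annual cost rows for one policy run."""

    scenario: Scenario
    clock: SimulationClock
    trajectory: Trajectory
    annual: pd.DataFrame  # one row per calendar year

    def year_row(self, year: int) -> pd.Series:
        rows = self.annual[self.annual["year"] == year]
        if rows.empty:
            raise ConfigurationError(f"year {year} not in result horizon")
        return rows.iloc[0]

    def t2dm_at(self, year: int) -> float:
        return float(self.year_row(year)[T2DM])

    def total_cost_at(self, year: int) -> float:
        return float(self.year_row(year)["cost_total"])


def _presets() -> dict[str, Scenario]:
    t2dm_prog = lambda **kw: ProgramSpec(target="t2dm", activation_year=2020, **kw)
    pre_prog = lambda **kw: ProgramSpec(target="prediabetes", activation_year=2020, **kw)
    return {
        "no_intervention": Scenario("no_intervention", []),
        "policy1_bariatric": Scenario(
            "policy1_bariatric",
            [ProgramSpec(
                name="bariatric_surgery", target="bariatric", activation_year=2020,
                fraction_recruited=0.28, success_rate=0.95, cost_multiplier=17.0,
            )],
        ),
        "policy2_reversediabetes2now": Scenario(
            "policy2_reversediabetes2now",
            [t2dm_prog(
                name="reversediabetes2now",
                fraction_recruited=0.002, fraction_recruited_final=0.30,
                ramp_years=10.0, success_rate=0.28, cost_multiplier=1.0,
            )],
        ),
        "policy3": Scenario(
            "policy3",
            [t2dm_prog(name="t2dm_program", fraction_recruited=0.3,
                       success_rate=0.3, cost_multiplier=1.0)],
        ),
        "policy4": Scenario(
            "policy4",
            [t2dm_prog(name="t2dm_program", fraction_recruited=0.45,
                       success_rate=0.3, cost_multiplier=2.0),
             pre_prog(name="prediabetes_program", fraction_recruited=0.3,
                      success_rate=0.3, cost_multiplier=1.0)],
        ),
        "policy5": Scenario(
            "policy5",
            [t2dm_prog(name="t2dm_program", fraction_recruited=0.6,
                       success_rate=0.5, cost_multiplier=3.0),
             pre_prog(name="prediabetes_program", fraction_recruited=0.4,
                      success_rate=0.5, cost_multiplier=3.0)],
        ),
        # narrative variants (table remains authoritative)
        "policy4_narrative": Scenario(
            "policy4_narrative",
            [t2dm_prog(name="t2dm_program", fraction_recruited=0.45,
                       success_rate=0.45, cost_multiplier=2.0),
             pre_prog(name="prediabetes_program", fraction_recruited=0.3,
                      success_rate=0.3, cost_multiplier=1.0)],
        ),
        "policy5_narrative": Scenario(
            "policy5_narrative",
            [t2dm_prog(name="t2dm_program", fraction_recruited=0.6,
                       success_rate=0.6, cost_multiplier=4.0)],
        ),
    }


#: scenario-run numbering of the published narrative
RUN_ALIASES = {
    "run1": "no_intervention",
    "run2": "policy1_bariatric",
    "run3": "policy2_reversediabetes2now",
    "run4": "policy3",
    "run5": "policy4",
    "run6": "policy5",
}


def preset_names() -> list[str]:
    return list(_presets())


def load_preset(name: str) -> Scenario:
    """Return the preset parameterization for ``name`` (or a runN alias)."""
    presets = _presets()
    key = RUN_ALIASES.get(name, name)
    if key not in presets:
        raise ConfigurationError(
            f"unknown preset {name!r}; available presets: "
            + ", ".join(sorted(presets) + sorted(RUN_ALIASES))
        )
    return presets[key]


def run_scenario(
    scenario: Scenario,
    journey_params: JourneyParameters,
    cost_params: CostParameters,
    clock: SimulationClock,
    initial: JourneyState | None = None,
) -> ScenarioResult:
    """Deterministic end-to-end run of one scenario.

    Builds the journey system with the scenario's program flows (the active
    T2DM program's relapse behaviour governs the shared no-medicine stock),
    integrates it, and derives one annual row per calendar year holding the
    end-of-December stocks, the realized program recruitment, and the
    payer-decomposed cost.
    """
    params = replace(
        journey_params, relapse=resolve_relapse(scenario.programs, journey_params)
    )
    program_flows = build_program_flows(scenario.programs, clock)
    system = build_journey_system(params, clock, program_flows, initial=initial)
    trajectory = integrate(system, clock)

    steps_per_year = round(12 / clock.dt_months)
    rows = []
    cumulative = 0.0
    for year in clock.report_years():
        idx = clock.year_index(year)
        state = {s: trajectory.stocks[s][idx] for s in trajectory.stocks}
        recruit_pairs = []
        recruits_by_program = {}
        for spec in scenario.programs:
            fname = f"recruitment[{spec.name}]"
            if fname in trajectory.flows:
                rates = trajectory.flows[fname][idx - steps_per_year:idx]
                recruits = float(np.sum(rates) * clock.dt_months)
            else:
                recruits = 0.0
            recruit_pairs.append((spec, recruits))
            recruits_by_program[spec.name] = recruits
        breakdown = annual_cost(state, cost_params, recruit_pairs, year)
        cumulative += breakdown.total
        row = {"year": year, **{s: state[s] for s in trajectory.stocks}}
        row.update({f"cost_{k}": v for k, v in breakdown.as_dict().items()})
        row["cost_cumulative"] = cumulative
        for pname, rec in recruits_by_program.items():
            row[f"recruits[{pname}]"] = rec
        rows.append(row)
    annual = pd.DataFrame(rows)
    assert np.allclose(
        annual["cost_cumulative"].to_numpy(),
        cumulative_cost(annual["cost_total"].to_numpy()),
    )
    return ScenarioResult(scenario, clock, trajectory, annual)


def compare(
    results: Sequence[ScenarioResult], report_years: Sequence[int]
) -> pd.DataFrame:
    """Tabulate T2DM stock, annual and cumulative cost of each run against
    the first result (the reference) at each report year."""
    if not results:
        raise ConfigurationError("no results to compare")
    ref = results[0]
    for r in results[1:]:
        if r.clock != ref.clock:
            raise ConfigurationError("results were run on different clocks")
    rows = []
    for r in results:
        for year in report_years:
            row = r.year_row(year)
            ref_row = ref.year_row(year)
            rows.append({
                "scenario": r.scenario.name,
                "year": year,
                "t2dm": float(row[T2DM]),
                "cost_total": float(row["cost_total"]),
                "cost_cumulative": float(row["cost_cumulative"]),
                "t2dm_vs_ref": float(row[T2DM] - ref_row[T2DM]),
                "cost_total_vs_ref": float(row["cost_total"] - ref_row["cost_total"]),
                "cost_cumulative_vs_ref": float(
                    row["cost_cumulative"] - ref_row["cost_cumulative"]
                ),
            })
    return pd.DataFrame(rows)


# -- configuration (de)serialization ----------------------------------------

def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "name": scenario.name,
        "programs": [
            {
                "name": p.name,
                "target": p.target,
                "active": p.active,
                "activation_year": p.activation_year,
                "fraction_recruited": p.fraction_recruited,
                "fraction_recruited_final": p.fraction_recruited_final,
                "ramp_years": p.ramp_years,
                "success_rate": p.success_rate,
                "cost_multiplier": p.cost_multiplier,
                "capacity": p.capacity,
                "relapse_fraction": p.relapse_fraction,
                "relapse_time": p.relapse_time,
            }
            for p in scenario.programs
        ],
        "overrides": dict(scenario.overrides),
    }


def scenario_from_dict(data: Mapping) -> Scenario:
    programs = [ProgramSpec(**p) for p in data.get("programs", [])]
    return Scenario(
        name=data["name"],
        programs=programs,
        overrides=dict(data.get("overrides", {})),
    )


def dump_config(config: Mapping) -> str:
    """Serialize a run configuration to canonical YAML (stable key order,
    so serialize -> parse -> serialize round-trips byte-identically)."""
    return yaml.safe_dump(dict(config), sort_keys=True, default_flow_style=False)


def load_config(text: str) -> dict:
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError("configuration must be a mapping")
    return data
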