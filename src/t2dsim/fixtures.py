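"""Deterministically generated inputs: default configuration, demographic
series, reference anchors and small closed-form toy systems.

No downloads and no bundled binaries: every input the simulator needs is
built here from the handful of published national statistics.  The
population trend linearly interpolates the printed prevalence anchors
(160 k diabetes patients being 1% of the population in 1990, 830 k being
~4.9% in 2011, and 1.2 M being 6.6% of ~18.2 M near the present day) and
extends flat thereafter, since no projection table is reproduced in the
source material.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .costs import CostParameters
from .engine import EXTERNAL, Flow, SimulationClock, StockFlowSystem
from .journey import (
    DEFAULT_RAPID_ONSET_SHARE, ConfigurationError, JourneyParameters,
    Transition,
)
from .scenarios import dump_config

__all__ = [
    "DemographicSeries", "default_demographics", "default_parameters",
    "default_cost_parameters", "default_clock", "default_config",
    "journey_params_from_config", "cost_params_from_config",
    "clock_from_config", "toy_system", "write_fixtures",
]

#: population anchors implied by printed prevalence statements
POPULATION_ANCHORS = {1990: 16.0e6, 2011: 16.9e6, 2018: 18.2e6, 2035: 18.2e6}


@dataclass
class DemographicSeries:
    """Yearly exogenous series, 1990-2035 by default."""

    years: np.ndarray = field(
        default_factory=lambda: np.arange(1990, 2036)
    )
    population: np.ndarray = field(default_factory=lambda: np.array([]))
    overweight_fraction: np.ndarray = field(default_factory=lambda: np.array([]))
    obese_fraction: np.ndarray = field(default_factory=lambda: np.array([]))
    elderly_fraction: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        n = len(self.years)
        if self.population.size == 0:
            anchors = sorted(POPULATION_ANCHORS)
            self.population = np.interp(
                self.years, anchors, [POPULATION_ANCHORS[y] for y in anchors]
            )
        if self.overweight_fraction.size == 0:
            self.overweight_fraction = np.full(n, 0.51)
        if self.obese_fraction.size == 0:
            self.obese_fraction = np.full(n, 0.15)
        if self.elderly_fraction.size == 0:
            self.elderly_fraction = np.full(n, 0.5)
        if np.any(self.population <= 0):
            raise ConfigurationError("population trend must be strictly positive")
        rel_change = np.abs(np.diff(self.population)) / self.population[:-1]
        if np.any(rel_change >= 0.05):
            raise ConfigurationError("population trend must be smooth (<5%/yr)")

    def population_trend(self) -> dict[int, float]:
        return {int(y): float(p) for y, p in zip(self.years, self.population)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years,
            "population": self.population,
            "overweight_fraction": self.overweight_fraction,
            "obese_fraction": self.obese_fraction,
            "elderly_fraction": self.elderly_fraction,
        })


def default_demographics() -> DemographicSeries:
    return DemographicSeries()


def default_clock() -> SimulationClock:
    return SimulationClock(start_year=1990, end_year=2035, dt_months=1.0)


def default_parameters() -> JourneyParameters:
    demo = default_demographics()
    return JourneyParameters(population_trend=demo.population_trend())


def default_cost_parameters() -> CostParameters:
    return CostParameters()


# -- configuration emission ---------------------------------------------------

def _transitions_to_config(transitions: Mapping) -> dict:
    out = {}
    for (source, dest), tr in transitions.items():
        out[f"{source}->{dest}"] = {
            "fraction": tr.fraction, "avg_time_years": tr.avg_time_years,
        }
    return out


def _transitions_from_config(data: Mapping) -> dict:
    out = {}
    for key, row in data.items():
        source, dest = key.split("->")
        out[(source, dest)] = Transition(row["fraction"], row["avg_time_years"])
    return out


def default_config() -> dict:
    """Complete run configuration with per-parameter provenance tags.

    Provenance values: ``published`` (printed in the source material),
    ``trivial`` (definitional) or ``calibrated-placeholder`` (chosen by the
    documented calibration because the source value is not public).
    """
    params = default_parameters()
    costs = default_cost_parameters()
    demo = default_demographics()
    config = {
        "clock": {"start_year": 1990, "end_year": 2035, "dt_months": 1.0},
        "journey": {
            "transitions": _transitions_to_config(params.transitions),
            "ifg_fraction": params.ifg_fraction,
            "igt_fraction": params.igt_fraction,
            "healthy_life_expectancy": params.healthy_life_expectancy,
            "lifespan_shortening": dict(params.lifespan_shortening),
            "t2dm_fraction_of_dm": params.t2dm_fraction_of_dm,
            "anchor_year": params.anchor_year,
            "anchor_t2dm": params.anchor_t2dm,
            "population_trend": {
                int(y): float(p) for y, p in params.population_trend.items()
            },
            "overweight_fraction": 0.51,
            "obese_fraction": 0.15,
            "rapid_onset_share": DEFAULT_RAPID_ONSET_SHARE,
            "initial_prediabetic_scale": 0.0,
        },
        "costs": {
            "wia_iva_benefit": costs.wia_iva_benefit,
            "wga_benefit": costs.wga_benefit,
            "employer_salary_continuation": costs.employer_salary_continuation,
            "productivity_loss": costs.productivity_loss,
            "ambulatory_care": costs.ambulatory_care,
            "hospitalization": costs.hospitalization,
            "physiotherapy": costs.physiotherapy,
            "tools_devices": costs.tools_devices,
            "gp_care": costs.gp_care,
            "medication_standard": costs.medication_standard,
            "medication_elderly": costs.medication_elderly,
            "comorbidity": costs.comorbidity,
            "dm_management_orgs": costs.dm_management_orgs,
            "disability_fraction": costs.disability_fraction,
            "elderly_fraction": 0.5,
            "employment_fraction": costs.employment_fraction,
            "base_program_cost": costs.base_program_cost,
        },
        "programs": [],
        "output": {"report_years": [2020, 2025, 2030, 2035]},
        "provenance": {
            "journey.transitions": "published",
            "journey.healthy_life_expectancy": "published",
            "journey.lifespan_shortening": "published",
            "journey.t2dm_fraction_of_dm": "published",
            "journey.anchor_t2dm": "published",
            "journey.overweight_fraction": "published",
            "journey.obese_fraction": "published",
            "journey.population_trend": "published (interpolated anchors)",
            "journey.ifg_fraction": "calibrated-placeholder",
            "journey.igt_fraction": "calibrated-placeholder",
            "journey.rapid_onset_share": "calibrated-placeholder",
            "journey.initial_prediabetic_scale": "calibrated-placeholder",
            "costs.unit_costs": "calibrated-placeholder",
            "costs.disability_fraction": "calibrated-placeholder",
            "costs.elderly_fraction": "calibrated-placeholder",
            "costs.employment_fraction": "published (all patients employed)",
            "costs.base_program_cost": "calibrated-placeholder",
            "clock": "published (45-year horizon, monthly step)",
        },
    }
    return config


def journey_params_from_config(config: Mapping) -> JourneyParameters:
    data = dict(config["journey"])
    data["transitions"] = _transitions_from_config(data["transitions"])
    data["population_trend"] = {
        int(y): float(p) for y, p in data["population_trend"].items()
    }
    return JourneyParameters(**data)


def cost_params_from_config(config: Mapping) -> CostParameters:
    return CostParameters(**config["costs"])


def clock_from_config(config: Mapping) -> SimulationClock:
    return SimulationClock(**config["clock"])


def validate_config(config: Mapping) -> list[str]:
    """Validate a run configuration; returns a list of error strings."""
    errors: list[str] = []
    for section in ("clock", "journey", "costs"):
        if section not in config:
            errors.append(f"missing configuration section {section!r}")
    if errors:
        return errors
    for builder in (clock_from_config, journey_params_from_config, cost_params_from_config):
        try:
            builder(config)
        except (ConfigurationError, TypeError, KeyError, ValueError) as exc:
            errors.append(f"{builder.__name__}: {exc}")
    return errors


# -- toy systems with closed-form oracles ------------------------------------

def toy_system(name: str) -> tuple[StockFlowSystem, Callable[[float], dict[str, float]]]:
    """Small hand-checkable systems plus their analytic solution.

    ``decay``             S' = -S/tau, S0 = 1000, tau = 24 months.
    ``two_stock_transfer``  A -> B at rate A/tau; total conserved exactly.
    ``logistic_population`` births b*P against a carrying-capacity brake,
                            net growth b*P*(1 - P/K); levels off at K.
    The returned oracle maps time in months to exact stock values.
    """
    if name == "decay":
        tau, s0 = 24.0, 1000.0
        system = StockFlowSystem(
            stocks={"S": s0},
            flows=[Flow("decay", "S", EXTERNAL, lambda state, t: state["S"] / tau)],
        )
        return system, lambda t: {"S": s0 * math.exp(-t / tau)}
    if name == "two_stock_transfer":
        tau, a0 = 36.0, 500.0
        system = StockFlowSystem(
            stocks={"A": a0, "B": 0.0},
            flows=[Flow("transfer", "A", "B", lambda state, t: state["A"] / tau)],
        )
        return system, lambda t: {
            "A": a0 * math.exp(-t / tau),
            "B": a0 * (1.0 - math.exp(-t / tau)),
        }
    if name == "logistic_population":
        b, k, p0 = 0.02, 10_000.0, 500.0  # per month, persons, persons
        system = StockFlowSystem(
            stocks={"P": p0},
            flows=[
                Flow("births", EXTERNAL, "P", lambda state, t: b * state["P"]),
                Flow(
                    "deaths", "P", EXTERNAL,
                    lambda state, t: b * state["P"] * state["P"] / k,
                ),
            ],
        )
        return system, lambda t: {
            "P": k / (1.0 + (k / p0 - 1.0) * math.exp(-b * t))
        }
    raise ConfigurationError(
        f"unknown toy system {name!r}; expected decay, two_stock_transfer "
        f"or logistic_population"
    )


def write_fixtures(target_dir: str | Path) -> list[Path]:
    """Write the default config (YAML) and demographic series (CSV)."""
    target = Path(target_dir)
    target.mkdir(parents=True, exist_ok=True)
    written = []
    config_path = target / "default_config.yaml"
    config_path.write_text(dump_config(default_config()))
    written.append(config_path)
    demo_path = target / "demographics.csv"
    default_demographics().to_frame().to_csv(demo_path, index=False)
    written.append(demo_path)
    return written
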