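"""Intervention scenario definitions and multi-scenario orchestration.

Nine named strategies are supported: a base-case with no intervention, two
medication-uptake scenarios (odds of analgesic use multiplied by 2 or 3 in
targeted age/pain groups), two surgical-access scenarios (JRS hazard
multiplied by 2 or 3 in OA patients with pain >= 2), and four preventive
scenarios (annual BMI reduction of 0.1 to 1.0 units in everyone at BMI >= 25).
All interventions switch on in the configured start year (2020 by default)
at full strength.

Scenario runs share one initial population and common random numbers, so a
person untouched by an intervention predicate follows an identical
trajectory in every scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import DRUGS, ParameterSet

NO_AGE_LIMIT = (20, 200)


@dataclass(frozen=True)
class MedicationModifier:
    """Odds multiplier for one drug in one (pain, age) target group."""

    drug: str
    multiplier: float
    min_pain: int                    # applies when pain >= min_pain
    age_range: tuple = NO_AGE_LIMIT  # inclusive [lo, hi]
    max_pain: int = 5                # upper pain bound (subgroup analyses)


@dataclass(frozen=True)
class Scenario:
    """A named bundle of intervention modifiers with target predicates."""

    name: str
    start_year: int = 2020
    medication_modifiers: tuple = ()
    jrs_multiplier: float = 1.0
    jrs_min_pain: int = 2
    bmi_reduction: float = 0.0       # kg/m^2 per year while BMI >= threshold
    bmi_threshold: float = 25.0
    suppress_treatment: bool = False

    def __post_init__(self):
        if self.jrs_multiplier <= 0:
            raise ValueError("jrs_multiplier must be > 0")
        if self.bmi_reduction < 0:
            raise ValueError("bmi_reduction must be >= 0")
        for m in self.medication_modifiers:
            if m.multiplier <= 0:
                raise ValueError("medication odds multipliers must be > 0")
            if m.drug not in DRUGS:
                raise ValueError(f"unknown drug {m.drug!r}")

    @property
    def is_prevention(self) -> bool:
        return self.bmi_reduction > 0


def _medication_modifiers(multiplier: float) -> tuple:
    """The targeted uptake pattern: acetaminophen at pain >= 2 for all ages;
    NSAIDs and coxibs at pain >= 2 for ages 20-69 but pain >= 3 at 70+;
    opioids at pain >= 3 for all ages (groups in which average benefit
    exceeds harm under the model)."""
    mods = [MedicationModifier("acetaminophen", multiplier, 2, NO_AGE_LIMIT)]
    for drug in ("nsaid", "coxib"):
        mods.append(MedicationModifier(drug, multiplier, 2, (20, 69)))
        mods.append(MedicationModifier(drug, multiplier, 3, (70, 200)))
    mods.append(MedicationModifier("opioid", multiplier, 3, NO_AGE_LIMIT))
    return tuple(mods)


SCENARIO_NAMES = ("Base-case", "Medication x2", "Medication x3",
                  "Surgery x2", "Surgery x3",
                  "BMI-0.1", "BMI-0.3", "BMI-0.5", "BMI-1.0")


def build_scenario(name: str, start_year: int = 2020) -> Scenario:
    """The named strategy-comparison scenario; raises on unrecognised names."""
    if name == "Base-case":
        return Scenario(name=name, start_year=start_year)
    if name in ("Medication x2", "Medication x3"):
        m = float(name.split("x")[1])
        return Scenario(name=name, start_year=start_year,
                        medication_modifiers=_medication_modifiers(m))
    if name in ("Surgery x2", "Surgery x3"):
        m = float(name.split("x")[1])
        return Scenario(name=name, start_year=start_year,
                        jrs_multiplier=m, jrs_min_pain=2)
    if name.startswith("BMI-") and name in SCENARIO_NAMES:
        return Scenario(name=name, start_year=start_year,
                        bmi_reduction=float(name.split("-")[1]))
    raise ValueError(
        f"unknown scenario {name!r}; valid names: {list(SCENARIO_NAMES)}")


def build_suppressed_treatment_scenario(start_year: int = 2020) -> Scenario:
    """Counterfactual with all drug and surgery effects switched off; its
    person-time difference vs base-case yields total OA-related YLLs."""
    return Scenario(name="Suppressed-treatment", start_year=start_year,
                    suppress_treatment=True)


def run_scenarios(ps: ParameterSet, scenarios, n: int, years: int, seed: int,
                  start_year: int = 2020, collect_events: bool = False) -> dict:
    """Simulate each scenario from one shared initial population under common
    random numbers; returns {scenario name: person-year table}.

    The base-case is added automatically if absent.  ``years`` is the horizon
    length (simulated calendar years start_year .. start_year + years - 1).
    """
    from .engine import simulate
    from .population import initialize_population

    if years <= 0:
        raise ValueError("horizon must be positive")
    scenarios = list(scenarios)
    # names resolve with the default intervention start (2020): the simulation
    # may begin earlier (burn-in) without moving the intervention onset
    resolved = [s if isinstance(s, Scenario) else build_scenario(s)
                for s in scenarios]
    if not any(s.name == "Base-case" for s in resolved):
        resolved.insert(0, build_scenario("Base-case"))
    init = initialize_population(ps, n, start_year, seed)
    out = {}
    for sc in resolved:
        out[sc.name] = simulate(ps, sc, init.copy(), years,
                                collect_events=collect_events)
    return out


def preliminary_subgroup_analysis(ps: ParameterSet, candidates, n: int,
                                  years: int, seed: int,
                                  start_year: int = 2020) -> pd.DataFrame:
    """Per-subgroup QALY impact of single-cell uptake modifiers vs base-case.

    ``candidates`` is an iterable of (drug, multiplier, (age_lo, age_hi),
    (pain_lo, pain_hi)) cells.  Each cell becomes a scenario whose odds
    multiplier applies only within that cell; the returned table reports the
    total QALY difference vs base-case accumulated inside the cell's age
    group (common random numbers make the differences exact for everyone the
    predicate never touches).
    """
    from .engine import simulate
    from .population import initialize_population

    init = initialize_population(ps, n, start_year, seed)
    base = simulate(ps, build_scenario("Base-case", start_year), init.copy(), years)
    rows = []
    for drug, mult, age_range, pain_range in candidates:
        pain_lo, pain_hi = pain_range
        mods = (MedicationModifier(drug, mult, int(pain_lo), tuple(age_range),
                                   max_pain=int(pain_hi)),)
        sc = Scenario(name=f"{drug} x{mult} pain{pain_lo}-{pain_hi} "
                           f"age{age_range[0]}-{age_range[1]}",
                      start_year=start_year,
                      medication_modifiers=mods)
        tab = simulate(ps, sc, init.copy(), years)
        q_scen = _group_qalys(tab, age_range)
        q_base = _group_qalys(base, age_range)
        rows.append({"drug": drug, "multiplier": mult,
                     "age_lo": age_range[0], "age_hi": age_range[1],
                     "pain_lo": pain_lo, "pain_hi": pain_hi,
                     "delta_qaly": q_scen - q_base})
    return pd.DataFrame(rows)


def _group_qalys(table: pd.DataFrame, age_range) -> float:
    if age_range[0] >= 70:
        sub = table[table["age_group"] == "70+"]
    elif age_range[1] <= 69:
        sub = table[table["age_group"] == "20-69"]
    else:
        sub = table
    return float((sub["util_pt_oa"] + sub["util_pt_nonoa"]).sum())
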