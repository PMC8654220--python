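"""Synthetic open population: initial cohort and demographic dynamics.

The population is stored as a structure of arrays for speed; ``Individual``
offers a one-person view matching the conceptual record (demographics, BMI,
OA status, HUI3 levels, medications, comorbidities, surgical history, vital
status).  People enter by turning 20 or immigrating and leave by death or
emigration; entry counts are exogenous fractions of the initial size.

All covariate draws are keyed by person id through the counter-based RNG, so
a given id receives identical initial characteristics in every scenario run
that shares a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import rng
from .params import (AGES, ATTRIBUTES, COMORBIDITIES, DRUGS, ParameterSet,
                     SEXES, calibrate_steady_state_prevalence)
from .hui3 import NO_YEAR
from .rng import Process


@dataclass
class Individual:
    """One simulated person's state (a copy, not a live view)."""

    id: int
    sex: str
    age: int
    education: int
    income: int
    region: int
    smoking: str
    bmi: float
    has_oa: bool
    oa_onset_year: int | None
    hui3: tuple
    meds: dict
    comorbidities: dict
    n_primary_jrs: int
    n_revision_jrs: int
    last_jrs_year: int | None
    alive: bool
    in_population: bool


SMOKING_LEVELS = ("never", "former", "current")


class Population:
    """Struct-of-arrays container for the simulated open population."""

    def __init__(self, calendar_year: int, seed: int, initial_n: int):
        self.calendar_year = calendar_year
        self.seed = seed
        self.initial_n = initial_n
        self.next_id = 0
        # fixed JRS attribute-odds normaliser, set at initialisation so every
        # scenario (and stepwise re-simulation) shares the same constant
        self.jrs_modifier_norm: float | None = None
        n = 0
        self.ids = np.empty(n, dtype=np.int64)
        self.sex = np.empty(n, dtype=np.int8)          # 0 male, 1 female
        self.age = np.empty(n, dtype=np.int16)
        self.education = np.empty(n, dtype=np.int8)    # 1..4
        self.income = np.empty(n, dtype=np.int8)       # 1..5
        self.region = np.empty(n, dtype=np.int8)       # 0..4
        self.smoking = np.empty(n, dtype=np.int8)      # 0 never/1 former/2 current
        self.bmi = np.empty(n, dtype=np.float64)
        self.has_oa = np.empty(n, dtype=bool)
        self.oa_onset_year = np.empty(n, dtype=np.int64)
        self.hui3 = np.empty((n, 8), dtype=np.int8)    # 1-based levels (pain as reported)
        self.pain_base = np.empty(n, dtype=np.int8)    # pain without the drug overlay
        self.meds = np.zeros((n, 4), dtype=bool)
        self.comorb = np.zeros((n, 6), dtype=bool)
        self.n_primary_jrs = np.zeros(n, dtype=np.int8)
        self.n_revision_jrs = np.zeros(n, dtype=np.int16)
        self.last_jrs_year = np.empty(n, dtype=np.int64)
        self.alive = np.empty(n, dtype=bool)
        self.in_pop = np.empty(n, dtype=bool)

    _ARRAYS = ("ids", "sex", "age", "education", "income", "region", "smoking",
               "bmi", "has_oa", "oa_onset_year", "hui3", "pain_base", "meds",
               "comorb", "n_primary_jrs", "n_revision_jrs", "last_jrs_year",
               "alive", "in_pop")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def active(self) -> np.ndarray:
        return self.alive & self.in_pop

    def copy(self) -> "Population":
        out = Population(self.calendar_year, self.seed, self.initial_n)
        out.next_id = self.next_id
        out.jrs_modifier_norm = self.jrs_modifier_norm
        for name in self._ARRAYS:
            setattr(out, name, getattr(self, name).copy())
        return out

    def append(self, other: "Population") -> None:
        for name in self._ARRAYS:
            setattr(self, name,
                    np.concatenate([getattr(self, name), getattr(other, name)]))

    def get_individual(self, i: int) -> Individual:
        onset = int(self.oa_onset_year[i])
        jrs = int(self.last_jrs_year[i])
        return Individual(
            id=int(self.ids[i]), sex=SEXES[self.sex[i]], age=int(self.age[i]),
            education=int(self.education[i]), income=int(self.income[i]),
            region=int(self.region[i]), smoking=SMOKING_LEVELS[self.smoking[i]],
            bmi=float(self.bmi[i]), has_oa=bool(self.has_oa[i]),
            oa_onset_year=None if onset == NO_YEAR else onset,
            hui3=tuple(int(v) for v in self.hui3[i]),
            meds={d: bool(self.meds[i, j]) for j, d in enumerate(DRUGS)},
            comorbidities={c: bool(self.comorb[i, j])
                           for j, c in enumerate(COMORBIDITIES)},
            n_primary_jrs=int(self.n_primary_jrs[i]),
            n_revision_jrs=int(self.n_revision_jrs[i]),
            last_jrs_year=None if jrs == NO_YEAR else jrs,
            alive=bool(self.alive[i]), in_population=bool(self.in_pop[i]),
        )


def _categorical(u: np.ndarray, probs) -> np.ndarray:
    return np.searchsorted(np.cumsum(np.asarray(probs, dtype=float)), u,
                           side="right").astype(np.int8)


def _entrant_mean_log(ps: ParameterSet, sex: str, year: int) -> float:
    """Initial log-BMI mean with the secular trend applied (the AR model's
    stationary mean shifts by year_coef/(1-lag) per calendar year)."""
    bm = ps.bmi_model[sex]
    drift = bm.year_coef / max(1.0 - bm.lag_coef, 1e-9)
    return bm.init_mean_log + drift * (year - 2020)


def generate_members(ps: ParameterSet, ids: np.ndarray, year: int, seed: int,
                     ages: np.ndarray | None = None,
                     assign_oa: bool = True) -> Population:
    """Draw fresh members (initial cohort, 20-year-old entrants, immigrants).

    Covariates come from the configured marginals; OA status, when assigned,
    follows the calibrated steady-state age/sex prevalence; HUI3 levels come
    from the baseline distributions conditional on OA and age.
    """
    d = ps.demography
    n = len(ids)
    pop = Population(year, seed, n)
    pop.ids = np.asarray(ids, dtype=np.int64)
    pop.sex = (rng.uniforms(seed, Process.INIT_SEX, year, ids) < d.sex_split
               ).astype(np.int8)
    if ages is None:
        pyramid = np.asarray(d.age_pyramid, dtype=float)
        u = rng.uniforms(seed, Process.INIT_AGE, year, ids)
        ages = AGES[_categorical(u, pyramid / pyramid.sum()).astype(np.int64)]
    pop.age = np.asarray(ages, dtype=np.int16)
    pop.education = 1 + _categorical(
        rng.uniforms(seed, Process.INIT_EDU, year, ids), d.education_probs)
    pop.income = 1 + _categorical(
        rng.uniforms(seed, Process.INIT_INCOME, year, ids), d.income_probs)
    pop.region = _categorical(
        rng.uniforms(seed, Process.INIT_REGION, year, ids), d.region_probs)
    pop.smoking = _categorical(
        rng.uniforms(seed, Process.INIT_SMOKING, year, ids), d.smoking_probs)

    z = rng.normals(seed, Process.INIT_BMI, year, ids)
    mean_log = np.where(pop.sex == 0,
                        _entrant_mean_log(ps, "male", year),
                        _entrant_mean_log(ps, "female", year))
    sd_log = np.where(pop.sex == 0, ps.bmi_model["male"].init_sd_log,
                      ps.bmi_model["female"].init_sd_log)
    pop.bmi = np.clip(np.exp(mean_log + sd_log * z), 12.0, 70.0)

    pop.oa_onset_year = np.full(n, NO_YEAR, dtype=np.int64)
    if assign_oa:
        prev = calibrate_steady_state_prevalence(ps)
        p = np.where(pop.sex == 0,
                     np.interp(pop.age, prev["age"], prev["male"]),
                     np.interp(pop.age, prev["age"], prev["female"]))
        pop.has_oa = rng.uniforms(seed, Process.INIT_OA, year, ids) < p
        # Onset year back-dated by half the mean accumulation span so OA-stage
        # splits (<5 vs >=5 years) are populated from the start.
        dur = np.maximum(1, ((pop.age - 20) * 0.4).astype(np.int64))
        pop.oa_onset_year[pop.has_oa] = year - dur[pop.has_oa]
    else:
        pop.has_oa = np.zeros(n, dtype=bool)

    # Prior surgical history for the prevalent OA pool, so post-JRS stages
    # (and revision eligibility) are populated from the first simulated year.
    pop.n_primary_jrs = np.zeros(n, dtype=np.int8)
    pop.n_revision_jrs = np.zeros(n, dtype=np.int16)
    pop.last_jrs_year = np.full(n, NO_YEAR, dtype=np.int64)
    if assign_oa and pop.has_oa.any():
        u = rng.uniforms(seed, Process.INIT_JRS, year, ids)
        dur_oa = (year - pop.oa_onset_year).astype(float)
        p_prior = np.where(pop.has_oa, np.clip(0.03 * dur_oa, 0.0, 0.55), 0.0)
        prior = u < p_prior
        pop.n_primary_jrs[prior] = 1
        u_y = rng.uniforms(seed, Process.INIT_JRS_YEAR, year, ids)
        since = (u_y * np.maximum(dur_oa, 1.0)).astype(np.int64)
        pop.last_jrs_year[prior] = year - since[prior]

    pop.comorb = np.zeros((n, 6), dtype=bool)
    for j, flag in enumerate(COMORBIDITIES):
        base, slope = d.comorbidity_init[flag]
        prob = np.clip(base + slope * (pop.age - 50.0), 0.0, 0.8)
        u = rng.uniforms(seed, Process.INIT_COMORB + j, year, ids)
        pop.comorb[:, j] = u < prob

    old = pop.age >= 65
    pop.hui3 = np.empty((n, 8), dtype=np.int8)
    for j, attr in enumerate(ATTRIBUTES):
        u = rng.uniforms(seed, Process.INIT_HUI3 + j, year, ids)
        levels = np.empty(n, dtype=np.int8)
        for oa_flag in (False, True):
            for old_flag in (False, True):
                key = ("oa_" if oa_flag else "nonoa_") + ("old" if old_flag else "young")
                mask = (pop.has_oa == oa_flag) & (old == old_flag)
                probs = ps.hui3_init[attr][key]
                levels[mask] = 1 + _categorical(u[mask], probs)
        pop.hui3[:, j] = levels
    pop.pain_base = pop.hui3[:, ATTRIBUTES.index("pain")].copy()

    pop.meds = np.zeros((n, 4), dtype=bool)
    pop.alive = np.ones(n, dtype=bool)
    pop.in_pop = np.ones(n, dtype=bool)
    return pop


def initialize_population(ps: ParameterSet, n: int, start_year: int,
                          seed: int) -> Population:
    """The initial cohort: ``n`` members aged 20+ with calibrated OA prevalence."""
    if n <= 0:
        raise ValueError("population size must be positive")
    ids = np.arange(n, dtype=np.int64)
    pop = generate_members(ps, ids, start_year, seed)
    pop.initial_n = n
    pop.next_id = n
    pop.calendar_year = start_year
    from .treatment import attr_odds_modifier
    oa = pop.has_oa & pop.active
    pop.jrs_modifier_norm = (
        float(attr_odds_modifier(ps.jrs_model,
                                 pop.hui3[oa].astype(np.int64)).mean())
        if oa.any() else 1.0)
    return pop


def death_probability(ps: ParameterSet, age, sex_idx, year, comorb=None) -> np.ndarray:
    """Background annual death probability from the age/sex/year mortality
    table, multiplied by configured comorbidity relative risks."""
    d = ps.demography
    q_table = np.stack([np.asarray(d.mortality[s], dtype=float) for s in SEXES])
    age_idx = np.clip(np.asarray(age, dtype=np.int64) - 20, 0, len(AGES) - 1)
    q = q_table[np.asarray(sex_idx), age_idx]
    q = q * d.mortality_year_factor ** (year - 2020)
    if comorb is not None:
        for j, flag in enumerate(COMORBIDITIES):
            rr = d.comorbidity_mortality_rr.get(flag, 1.0)
            if rr != 1.0:
                q = q * np.where(comorb[:, j], rr, 1.0)
    return np.clip(q, 0.0, 1.0)


def sample_background_death(ps: ParameterSet, age, sex_idx, year, u,
                            comorb=None) -> np.ndarray:
    """Bernoulli death indicator at the table probability for (age, sex, year)."""
    return np.asarray(u) < death_probability(ps, age, sex_idx, year, comorb)


def advance_demographics(pop: Population, ps: ParameterSet) -> dict:
    """One annual demographic step: aging, background death, emigration, entry.

    Mutates ``pop`` in place and returns the event tally
    {deaths, emigrants, entrants, immigrants}.  New entrants join at the start
    of the year and are not exposed to death within their entry year.
    """
    year = pop.calendar_year
    seed = pop.seed
    active = pop.active
    pop.age[active] += 1

    idx = np.flatnonzero(active)
    u = rng.uniforms(seed, Process.DEATH, year, pop.ids[idx])
    died = sample_background_death(ps, pop.age[idx], pop.sex[idx], year, u,
                                   pop.comorb[idx])
    pop.alive[idx[died]] = False

    survivors = idx[~died]
    u = rng.uniforms(seed, Process.EMIGRATION, year, pop.ids[survivors])
    emigrated = u < ps.demography.emigration_rate
    pop.in_pop[survivors[emigrated]] = False

    n_entrants = int(round(ps.demography.entry_rate * pop.initial_n))
    n_immigrants = int(round(ps.demography.immigration_rate * pop.initial_n))
    if n_entrants:
        ids = np.arange(pop.next_id, pop.next_id + n_entrants, dtype=np.int64)
        pop.next_id += n_entrants
        newcomers = generate_members(ps, ids, year, seed,
                                     ages=np.full(n_entrants, 20),
                                     assign_oa=False)
        pop.append(newcomers)
    if n_immigrants:
        ids = np.arange(pop.next_id, pop.next_id + n_immigrants, dtype=np.int64)
        pop.next_id += n_immigrants
        lo, hi = ps.demography.immigrant_age_range
        u_age = rng.uniforms(seed, Process.INIT_AGE, year, ids)
        ages = (lo + u_age * (hi - lo)).astype(np.int64)
        immigrants = generate_members(ps, ids, year, seed, ages=ages)
        pop.append(immigrants)

    return {"deaths": int(died.sum()), "emigrants": int(emigrated.sum()),
            "entrants": n_entrants, "immigrants": n_immigrants}


def snapshot_frame(pop: Population):
    """Population snapshot as a DataFrame, one row per person (documented
    column order for the per-person-year CSV export)."""
    import pandas as pd

    return pd.DataFrame({
        "id": pop.ids, "year": pop.calendar_year,
        "sex": np.asarray(SEXES)[pop.sex], "age": pop.age,
        "bmi": np.round(pop.bmi, 3), "has_oa": pop.has_oa,
        "pain": pop.hui3[:, ATTRIBUTES.index("pain")],
        **{f"med_{d}": pop.meds[:, j] for j, d in enumerate(DRUGS)},
        "n_primary_jrs": pop.n_primary_jrs,
        "n_revision_jrs": pop.n_revision_jrs,
        "alive": pop.alive, "in_population": pop.in_pop,
    })
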