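"""Model parameters: types, synthetic defaults, file I/O, calibration, perturbation.

The parameter set covers every coefficient the simulation consumes: demographic
rates, the sex-specific autoregressive log-BMI model, osteoarthritis (OA)
incidence by age band and sex with BMI relative risks, proportional-odds models
for the eight HUI3 attributes, a multiplicative utility map, medication
point-prevalence tables by age band x sex x OA stage x pain level, drug pain
effects and side-effect rates, treatment case fatality, and the joint
replacement surgery (JRS) Poisson model.

The default set is synthetic but structure-complete.  It was chosen so the
base-case population resembles published Canadian OA figures in order of
magnitude (OA prevalence roughly 12-17%, NSAID use among OA near 38%, primary
JRS around 40-55 per 1000 OA person-years) and so that net benefit/harm of
analgesics varies by age and pain level in the direction that motivates
targeted uptake scenarios.  Every coefficient can be overridden through the
YAML parameter file.
"""

from __future__ import annotations

import copy
import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import yaml
from scipy.stats import norm

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

# Field-wide categorical layouts, shared by all modules.
SEXES = ("male", "female")
DRUGS = ("acetaminophen", "nsaid", "coxib", "opioid")
ATTRIBUTES = ("vision", "hearing", "speech", "mobility", "dexterity",
              "emotion", "cognition", "pain")
COMORBIDITIES = ("diabetes", "hypertension", "cvd", "stroke", "ulcer", "dyspepsia")
OA_STAGES = ("oa_lt5", "oa_ge5", "postjrs_lt5", "postjrs_ge5")
BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")

# 5-year age bands, half-open [a, a+5), top band 90+.
AGE_BAND_EDGES = np.arange(20, 95, 5)
N_AGE_BANDS = len(AGE_BAND_EDGES)  # 15
MAX_AGE = 100
AGES = np.arange(20, MAX_AGE + 1)
N_PAIN_LEVELS = 5


def age_band_index(age) -> np.ndarray:
    """Index of the 5-year age band containing ``age`` (90+ is the top band)."""
    a = np.asarray(age)
    return np.clip((a - 20) // 5, 0, N_AGE_BANDS - 1).astype(np.int64)


class ParameterError(ValueError):
    """Malformed or invariant-violating parameter input."""


class CalibrationError(RuntimeError):
    """Steady-state calibration failed to converge."""


class TitrationError(RuntimeError):
    """Rate titration could not reach the target within bounds."""


# ---------------------------------------------------------------------------
# Component dataclasses
# ---------------------------------------------------------------------------

@dataclass
class Demography:
    """Open-population dynamics and initial covariate distributions."""

    entry_rate: float = 0.016          # annual 20-year-old entrants / initial pop
    immigration_rate: float = 0.006    # annual immigrants / initial pop
    emigration_rate: float = 0.002     # per person-year probability
    # Background mortality q(age) per sex, ages 20..100 (81 values each).
    mortality: dict = field(default_factory=dict)   # sex -> list[float]
    mortality_year_factor: float = 0.997            # annual improvement multiplier
    comorbidity_mortality_rr: dict = field(default_factory=dict)
    age_pyramid: list = field(default_factory=list)  # weights for ages 20..100
    sex_split: float = 0.5             # probability female
    education_probs: list = field(default_factory=lambda: [0.25, 0.30, 0.30, 0.15])
    income_probs: list = field(default_factory=lambda: [0.15, 0.20, 0.25, 0.25, 0.15])
    region_probs: list = field(default_factory=lambda: [0.30, 0.25, 0.20, 0.15, 0.10])
    smoking_probs: list = field(default_factory=lambda: [0.50, 0.30, 0.20])
    immigrant_age_range: list = field(default_factory=lambda: [20, 60])
    # Initial prevalence of each comorbidity flag: (prob at age 50, slope per year).
    comorbidity_init: dict = field(default_factory=dict)


@dataclass
class BmiSexModel:
    """Autoregressive model for log-BMI, one per sex.

    new log-BMI = intercept + lag_coef*log(bmi) + age_coef*(age-50)
                  + year_coef*(year-2020) + edu_coef*edu + income_coef*income
                  + region_coef*region + Normal(0, resid_sd)
    """

    intercept: float
    lag_coef: float
    age_coef: float = 0.0
    year_coef: float = 0.0
    edu_coef: float = 0.0
    income_coef: float = 0.0
    region_coef: float = 0.0
    resid_sd: float = 0.05
    init_mean_log: float = 3.28
    init_sd_log: float = 0.16


@dataclass
class OaIncidence:
    """OA onset hazard: base rate per 1000 person-years by age band and sex,
    multiplied by a BMI-category relative risk (normal weight = 1)."""

    base_per_1000: dict = field(default_factory=dict)  # sex -> 15 band values
    rr_bmi: dict = field(default_factory=dict)         # category -> [male, female]


@dataclass
class Hui3AttributeModel:
    """Proportional-odds model for one HUI3 attribute.

    The linear predictor pushes toward *worse* (higher) levels; category
    probabilities come from logistic differences at the cutpoints.
    """

    name: str
    n_levels: int
    cutpoints: list
    lag_coef: float = 0.0        # on (lagged own level - 1)
    age_coef: float = 0.0        # on (age - 50)
    sex_coef: float = 0.0        # female = 1
    year_coef: float = 0.0       # on (year - 2020)
    edu_coef: float = 0.0
    income_coef: float = 0.0
    smoking_coef: float = 0.0    # current smoker = 1
    bmi_coef: float = 0.0        # on (bmi - 25) / 5
    oa_coef: float = 0.0
    postjrs_coef: float = 0.0    # durable shift for post-JRS states
    comorb_coefs: dict = field(default_factory=dict)
    concurrent_coefs: dict = field(default_factory=dict)  # earlier attr -> coef on (level-1)


@dataclass
class UtilityMap:
    """Multiplicative multi-attribute utility: u = c * prod(factor) - (c - 1).

    Per-attribute level factors start at 1 (best level) and are nonincreasing,
    so the all-best vector scores exactly 1 and worsening any attribute never
    raises utility.  The floor is bounded below by -(c - 1).
    """

    constant: float = 1.36
    factors: dict = field(default_factory=dict)  # attr -> list per level


@dataclass
class MedicationModel:
    """Analgesic point prevalence and pain effects.

    ``prevalence[drug]`` has shape (2 sexes, 15 age bands, 4 OA stages,
    5 pain levels).  ``improve_prob``/``improve2_prob`` give the annual
    probability that a user's pain falls by one/two levels (placebo included).
    """

    prevalence: dict = field(default_factory=dict)        # drug -> nested lists
    background_nonoa: dict = field(default_factory=dict)  # drug -> prob for non-OA
    improve_prob: dict = field(default_factory=dict)      # drug -> P(1-level gain)
    improve2_prob: dict = field(default_factory=dict)     # drug -> P(2-level gain)


@dataclass
class SideEffectModel:
    """Annual side-effect processes tied to analgesic use.

    GI bleeds use excess rates among users; CVD and stroke use a baseline
    incidence (all adults, by age band) with user relative risks; dyspepsia is
    a user rate without mortality; opioid users face an overdose death
    probability (titratable against an observed national death count).
    """

    gi_excess: dict = field(default_factory=dict)       # drug -> excess rate
    dyspepsia_rate: dict = field(default_factory=dict)  # drug -> rate
    cvd_baseline: list = field(default_factory=list)    # per age band
    cvd_rr: dict = field(default_factory=dict)          # drug -> RR
    stroke_baseline: list = field(default_factory=list)
    stroke_rr: dict = field(default_factory=dict)
    opioid_overdose_death_prob: float = 0.009


@dataclass
class TreatmentMortality:
    """Case fatality of treatment-related events."""

    gi_cf: float = 0.12
    cvd_cf: float = 0.15
    stroke_cf: float = 0.20
    jrs_periop: float = 0.005


@dataclass
class JrsModel:
    """Joint replacement surgery rates and effects.

    Primary and revision rates follow log-linear (Poisson) models in age, sex
    and calendar year.  The hazard is additionally scaled by an HUI3
    attribute-level odds modifier, normalised so the initial OA population's
    average modifier is 1 (the marginal rate then matches the Poisson model).
    """

    primary_intercept: float = np.log(0.052)
    primary_age_coef: float = 0.015
    primary_female_coef: float = -0.10
    primary_year_coef: float = 0.008
    revision_intercept: float = np.log(0.012)
    revision_age_coef: float = 0.0
    revision_female_coef: float = -0.20
    revision_year_coef: float = 0.008
    ref_age: float = 70.0
    ref_year: int = 2020
    attr_odds: dict = field(default_factory=dict)   # attr -> OR per level
    pain_gain_probs: list = field(default_factory=lambda: [0.75, 0.1875, 0.0625])
    mobility_improve_prob: float = 0.3
    periop_ref: str = "treatment_mortality.jrs_periop"  # informational
    max_primaries: int = 4
    multiplier_applies_to_revision: bool = False


@dataclass
class ParameterSet:
    """Every coefficient and rate the simulation consumes, addressable by name."""

    schema_version: int = SCHEMA_VERSION
    demography: Demography = field(default_factory=Demography)
    bmi_model: dict = field(default_factory=dict)        # sex -> BmiSexModel
    oa_incidence: OaIncidence = field(default_factory=OaIncidence)
    hui3_models: dict = field(default_factory=dict)      # attr -> Hui3AttributeModel
    hui3_update_order: list = field(default_factory=list)
    hui3_init: dict = field(default_factory=dict)        # attr -> group -> probs
    utility_map: UtilityMap = field(default_factory=UtilityMap)
    medications: MedicationModel = field(default_factory=MedicationModel)
    side_effects: SideEffectModel = field(default_factory=SideEffectModel)
    treatment_mortality: TreatmentMortality = field(default_factory=TreatmentMortality)
    jrs_model: JrsModel = field(default_factory=JrsModel)
    parameter_uncertainty: dict = field(default_factory=dict)  # name -> dict

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def to_dict(self) -> dict:
        return _to_plain(dataclasses.asdict(self))


def _to_plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_plain(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# Default synthetic parameter set
# ---------------------------------------------------------------------------

def _default_age_pyramid() -> np.ndarray:
    """A 2001-Canada-like adult age pyramid: a mid-life bulge, then survival decay."""
    knots_age = np.array([20, 35, 45, 55, 65, 75, 85, 100])
    knots_w = np.array([1.00, 1.15, 1.15, 0.90, 0.72, 0.45, 0.18, 0.03])
    w = np.interp(AGES, knots_age, knots_w)
    return w / w.sum()


def _default_mortality() -> dict:
    """Gompertz-like background mortality q(age) per sex, ages 20..100."""
    q_male = np.minimum(0.7, 0.00022 * np.exp(0.088 * (AGES - 20)))
    q_female = np.minimum(0.7, 0.65 * 0.00022 * np.exp(0.090 * (AGES - 20)))
    return {"male": q_male.tolist(), "female": q_female.tolist()}


_DEFAULT_OA_BASE = {
    # per 1000 person-years, 15 five-year bands from 20-24 to 90+
    "male":   [0.32, 0.55, 0.82, 1.37, 2.28, 3.65, 5.75, 8.94, 12.6, 16.8,
               21.0, 24.2, 26.3, 27.3, 27.3],
    "female": [0.49, 0.84, 1.29, 2.13, 3.55, 5.68, 8.97, 13.9, 19.6, 26.1,
               32.7, 37.6, 40.9, 42.4, 42.4],
}

_NONPAIN_CUTPOINTS = [4.0, 6.5]

_DEFAULT_MED_PAIN_PREV = {
    # point prevalence by pain level 1..5, per sex, among people with OA
    "acetaminophen": {"male": [0.13, 0.22, 0.28, 0.33, 0.36],
                      "female": [0.19, 0.32, 0.40, 0.47, 0.52]},
    "nsaid": {"male": [0.32, 0.44, 0.52, 0.57, 0.60],
              "female": [0.33, 0.45, 0.53, 0.58, 0.61]},
    "coxib": {"male": [0.025, 0.06, 0.08, 0.10, 0.12],
              "female": [0.030, 0.07, 0.095, 0.12, 0.14]},
    "opioid": {"male": [0.02, 0.06, 0.10, 0.14, 0.18],
               "female": [0.025, 0.07, 0.12, 0.17, 0.21]},
}
_STAGE_FACTORS = [1.00, 1.05, 0.80, 0.70]
_AGE_FACTOR_KNOTS = ([20, 40, 60, 90], [0.90, 1.00, 1.05, 1.05])


def _build_med_prevalence() -> dict:
    band_mid = AGE_BAND_EDGES + 2.5
    age_f = np.interp(band_mid, *_AGE_FACTOR_KNOTS)
    prev = {}
    for drug in DRUGS:
        tab = np.zeros((2, N_AGE_BANDS, len(OA_STAGES), N_PAIN_LEVELS))
        for s, sex in enumerate(SEXES):
            base = np.asarray(_DEFAULT_MED_PAIN_PREV[drug][sex])
            tab[s] = (age_f[:, None, None]
                      * np.asarray(_STAGE_FACTORS)[None, :, None]
                      * base[None, None, :])
        prev[drug] = np.clip(tab, 0.0, 0.95).tolist()
    return prev


def _default_hui3_models() -> tuple[dict, list]:
    order = ["vision", "hearing", "speech", "cognition", "emotion",
             "mobility", "dexterity", "pain"]
    m = {}
    for attr in ATTRIBUTES:
        if attr == "pain":
            continue
        m[attr] = Hui3AttributeModel(
            name=attr, n_levels=3, cutpoints=list(_NONPAIN_CUTPOINTS),
            lag_coef=2.2,
            age_coef=0.020 if attr in ("vision", "hearing", "mobility",
                                       "dexterity", "cognition") else 0.0,
        )
    m["mobility"].oa_coef = 0.5
    m["dexterity"].oa_coef = 0.2
    m["emotion"].oa_coef = 0.2
    m["vision"].comorb_coefs = {"diabetes": 0.3}
    m["mobility"].comorb_coefs = {"stroke": 2.0, "cvd": 1.0}
    m["speech"].comorb_coefs = {"stroke": 0.5}
    m["cognition"].comorb_coefs = {"stroke": 1.2}
    m["dexterity"].comorb_coefs = {"stroke": 0.5}
    m["emotion"].comorb_coefs = {"cvd": 0.6, "dyspepsia": 0.5, "ulcer": 0.3}
    m["emotion"].concurrent_coefs = {"cognition": 0.3}
    m["pain"] = Hui3AttributeModel(
        name="pain", n_levels=5, cutpoints=[2.9, 3.5, 4.5, 5.7],
        lag_coef=1.6, age_coef=0.006, oa_coef=0.75, smoking_coef=0.1,
        sex_coef=0.12, postjrs_coef=-0.65,
        comorb_coefs={"ulcer": 0.5, "dyspepsia": 0.5},
        concurrent_coefs={"mobility": 0.2, "emotion": 0.1},
    )
    return m, order


def _default_hui3_init() -> dict:
    init = {}
    for attr in ATTRIBUTES:
        if attr == "pain":
            init[attr] = {
                "oa_young":    [0.74, 0.06, 0.09, 0.07, 0.04],
                "oa_old":      [0.70, 0.06, 0.10, 0.08, 0.06],
                "nonoa_young": [0.92, 0.04, 0.025, 0.010, 0.005],
                "nonoa_old":   [0.88, 0.05, 0.040, 0.020, 0.010],
            }
        else:
            init[attr] = {
                "oa_young":    [0.96, 0.03, 0.01],
                "oa_old":      [0.88, 0.09, 0.03],
                "nonoa_young": [0.97, 0.025, 0.005],
                "nonoa_old":   [0.90, 0.08, 0.02],
            }
    return init


_DEFAULT_UTILITY_FACTORS = {
    "vision":    [1.0, 0.95, 0.73],
    "hearing":   [1.0, 0.95, 0.74],
    "speech":    [1.0, 0.94, 0.68],
    "mobility":  [1.0, 0.92, 0.65],
    "dexterity": [1.0, 0.93, 0.68],
    "emotion":   [1.0, 0.91, 0.65],
    "cognition": [1.0, 0.92, 0.66],
    "pain":      [1.0, 0.975, 0.88, 0.75, 0.55],
}

_DEFAULT_COMORB_INIT = {
    "diabetes":     [0.040, 0.0020],
    "hypertension": [0.150, 0.0060],
    "cvd":          [0.030, 0.0040],
    "stroke":       [0.010, 0.0015],
    "ulcer":        [0.020, 0.0005],
    "dyspepsia":    [0.030, 0.0005],
}

_DEFAULT_CVD_BASELINE = [0.0002, 0.0003, 0.0005, 0.0008, 0.0013, 0.0020, 0.0032,
                         0.0050, 0.0075, 0.0144, 0.0275, 0.0350, 0.0450, 0.0550,
                         0.0625]


def build_default_parameters(seed: int = 1) -> ParameterSet:
    """Construct the complete synthetic default parameter set.

    The construction is deterministic; ``seed`` is accepted for interface
    stability (a future stochastic synthesiser would consume it) and does not
    alter the returned values.
    """
    int(seed)  # validates the argument

    demo = Demography(
        mortality=_default_mortality(),
        comorbidity_mortality_rr={"diabetes": 1.25, "hypertension": 1.10,
                                  "cvd": 1.40, "stroke": 1.60,
                                  "ulcer": 1.05, "dyspepsia": 1.00},
        age_pyramid=_default_age_pyramid().tolist(),
        comorbidity_init={k: list(v) for k, v in _DEFAULT_COMORB_INIT.items()},
    )

    bmi = {
        "male": BmiSexModel(intercept=(1 - 0.95) * 3.288, lag_coef=0.95,
                            year_coef=0.00008, resid_sd=0.050,
                            init_mean_log=3.288, init_sd_log=0.160),
        "female": BmiSexModel(intercept=(1 - 0.95) * 3.225, lag_coef=0.95,
                              year_coef=0.00008, resid_sd=0.0624,
                              init_mean_log=3.225, init_sd_log=0.200),
    }

    oa = OaIncidence(
        base_per_1000={s: list(v) for s, v in _DEFAULT_OA_BASE.items()},
        rr_bmi={"underweight": [0.9, 0.9], "normal": [1.0, 1.0],
                "overweight": [1.6, 1.6], "obese": [2.5, 2.5]},
    )

    hui3_models, order = _default_hui3_models()

    meds = MedicationModel(
        prevalence=_build_med_prevalence(),
        background_nonoa={d: 0.0 for d in DRUGS},
        improve_prob={"acetaminophen": 0.40, "nsaid": 0.25,
                      "coxib": 0.25, "opioid": 0.10},
        improve2_prob={"acetaminophen": 0.10, "nsaid": 0.30,
                       "coxib": 0.35, "opioid": 0.25},
    )

    se = SideEffectModel(
        gi_excess={"nsaid": 0.006, "coxib": 0.003, "opioid": 0.002},
        dyspepsia_rate={"nsaid": 0.10, "coxib": 0.12, "opioid": 0.10},
        cvd_baseline=list(_DEFAULT_CVD_BASELINE),
        cvd_rr={"nsaid": 1.5, "coxib": 2.0},
        stroke_baseline=[v / 2 for v in _DEFAULT_CVD_BASELINE],
        stroke_rr={"nsaid": 1.3, "coxib": 1.8},
        opioid_overdose_death_prob=0.009,
    )

    jrs = JrsModel(
        attr_odds={"pain": [0.5, 1.0, 2.5, 3.5, 5.0],
                   "mobility": [0.8, 1.0, 1.5]},
    )

    ps = ParameterSet(
        demography=demo, bmi_model=bmi, oa_incidence=oa,
        hui3_models=hui3_models, hui3_update_order=order,
        hui3_init=_default_hui3_init(),
        utility_map=UtilityMap(constant=1.36,
                               factors={k: list(v) for k, v in
                                        _DEFAULT_UTILITY_FACTORS.items()}),
        medications=meds, side_effects=se,
        treatment_mortality=TreatmentMortality(),
        jrs_model=jrs,
        parameter_uncertainty=_default_uncertainty(),
    )
    # Route every registered default through its own setter at the mean, so
    # perturb(name, "mean") is bit-identical to the shipped defaults.
    for name in ps.parameter_uncertainty:
        _REGISTRY[name](ps, ps.parameter_uncertainty[name]["mean"])
    validate_parameters(ps)
    return ps


# ---------------------------------------------------------------------------
# Sensitivity registry: 17 named parameters with 95% CI bounds
# ---------------------------------------------------------------------------

def _set_rr(cat):
    def setter(ps, v):
        ps.oa_incidence.rr_bmi[cat] = [v, v]
    return setter


def _set_pain_effect(drug):
    def setter(ps, v):
        ps.medications.improve_prob[drug] = v
    return setter


def _set_gi(drug):
    def setter(ps, v):
        ps.side_effects.gi_excess[drug] = v
    return setter


def _set_cvd_rr(drug):
    def setter(ps, v):
        ps.side_effects.cvd_rr[drug] = v
    return setter


def _set_stroke_rr(drug):
    def setter(ps, v):
        ps.side_effects.stroke_rr[drug] = v
    return setter


def _set_overdose(ps, v):
    ps.side_effects.opioid_overdose_death_prob = v


def _set_jrs_pain(ps, v):
    # v = probability of any post-JRS pain improvement; 1-vs-2 level split fixed
    ps.jrs_model.pain_gain_probs = [1.0 - v, 0.75 * v, 0.25 * v]


def _set_jrs_mobility(ps, v):
    ps.jrs_model.mobility_improve_prob = v


def _set_periop(ps, v):
    ps.treatment_mortality.jrs_periop = v


_REGISTRY: dict[str, Callable] = {
    "oa_rr_overweight": _set_rr("overweight"),
    "oa_rr_obese": _set_rr("obese"),
    "pain_effect_acetaminophen": _set_pain_effect("acetaminophen"),
    "pain_effect_nsaid": _set_pain_effect("nsaid"),
    "pain_effect_coxib": _set_pain_effect("coxib"),
    "pain_effect_opioid": _set_pain_effect("opioid"),
    "gi_excess_nsaid": _set_gi("nsaid"),
    "gi_excess_coxib": _set_gi("coxib"),
    "gi_excess_opioid": _set_gi("opioid"),
    "cvd_rr_nsaid": _set_cvd_rr("nsaid"),
    "cvd_rr_coxib": _set_cvd_rr("coxib"),
    "stroke_rr_nsaid": _set_stroke_rr("nsaid"),
    "stroke_rr_coxib": _set_stroke_rr("coxib"),
    "opioid_overdose_death_prob": _set_overdose,
    "jrs_pain_improvement": _set_jrs_pain,
    "jrs_mobility_improvement": _set_jrs_mobility,
    "jrs_perioperative_mortality": _set_periop,
}


def _default_uncertainty() -> dict:
    u = {
        "oa_rr_overweight": (1.6, 1.25, 2.0, "relative risk"),
        "oa_rr_obese": (2.5, 1.9, 3.2, "relative risk"),
        "pain_effect_acetaminophen": (0.40, 0.30, 0.50, "probability/year"),
        "pain_effect_nsaid": (0.25, 0.18, 0.33, "probability/year"),
        "pain_effect_coxib": (0.25, 0.18, 0.33, "probability/year"),
        "pain_effect_opioid": (0.10, 0.06, 0.15, "probability/year"),
        "gi_excess_nsaid": (0.006, 0.003, 0.009, "events/user-year"),
        "gi_excess_coxib": (0.003, 0.0015, 0.0045, "events/user-year"),
        "gi_excess_opioid": (0.002, 0.001, 0.003, "events/user-year"),
        "cvd_rr_nsaid": (1.5, 1.1, 1.9, "relative risk"),
        "cvd_rr_coxib": (2.0, 1.4, 2.7, "relative risk"),
        "stroke_rr_nsaid": (1.3, 1.0, 1.6, "relative risk"),
        "stroke_rr_coxib": (1.8, 1.2, 2.4, "relative risk"),
        "opioid_overdose_death_prob": (0.009, 0.005, 0.013, "probability/user-year"),
        "jrs_pain_improvement": (0.25, 0.12, 0.40, "probability"),
        "jrs_mobility_improvement": (0.30, 0.15, 0.45, "probability"),
        "jrs_perioperative_mortality": (0.005, 0.002, 0.009, "probability/surgery"),
    }
    return {k: {"mean": m, "lower95": lo, "upper95": hi, "units": un}
            for k, (m, lo, hi, un) in u.items()}


def registered_parameters(ps: ParameterSet) -> list[str]:
    """Names of all parameters in the one-way sensitivity registry."""
    return list(ps.parameter_uncertainty.keys())


def perturb_parameter(ps: ParameterSet, name: str, which: str) -> ParameterSet:
    """Copy of ``ps`` with the named parameter set to mean/lower/upper."""
    if name not in ps.parameter_uncertainty or name not in _REGISTRY:
        raise KeyError(
            f"unknown sensitivity parameter {name!r}; valid names: "
            f"{sorted(_REGISTRY)}")
    if which not in ("mean", "lower", "upper"):
        raise ValueError("which must be one of 'mean', 'lower', 'upper'")
    key = {"mean": "mean", "lower": "lower95", "upper": "upper95"}[which]
    out = ps.copy()
    _REGISTRY[name](out, ps.parameter_uncertainty[name][key])
    return out


def export_registry_csv(ps: ParameterSet, path) -> None:
    """Write the sensitivity registry as CSV (name, mean, lower95, upper95, units)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "mean", "lower95", "upper95", "units"])
        for name, entry in ps.parameter_uncertainty.items():
            w.writerow([name, entry["mean"], entry["lower95"],
                        entry["upper95"], entry["units"]])


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{key}: {msg}")


def validate_parameters(ps: ParameterSet) -> None:
    """Raise ParameterError naming the offending key on any invariant violation."""
    d = ps.demography
    for rate_name in ("entry_rate", "immigration_rate", "emigration_rate"):
        _check(getattr(d, rate_name) >= 0, f"demography.{rate_name}", "rate must be >= 0")
    for sex in SEXES:
        _check(sex in d.mortality, f"demography.mortality.{sex}", "missing sex")
        q = np.asarray(d.mortality[sex], dtype=float)
        _check(q.shape == AGES.shape, f"demography.mortality.{sex}",
               f"needs {len(AGES)} values for ages 20..{MAX_AGE}")
        _check(bool(np.all((q >= 0) & (q <= 1))), f"demography.mortality.{sex}",
               "probabilities must lie in [0, 1]")
    _check(len(d.age_pyramid) == len(AGES), "demography.age_pyramid",
           f"needs {len(AGES)} weights")
    _check(all(w >= 0 for w in d.age_pyramid), "demography.age_pyramid",
           "weights must be >= 0")
    for pname in ("education_probs", "income_probs", "region_probs", "smoking_probs"):
        p = np.asarray(getattr(d, pname), dtype=float)
        _check(bool(np.all(p >= 0)) and abs(p.sum() - 1) < 1e-6,
               f"demography.{pname}", "must be a probability vector")

    for sex in SEXES:
        _check(sex in ps.bmi_model, f"bmi_model.{sex}", "missing sex")
        bm = ps.bmi_model[sex]
        _check(bm.resid_sd >= 0, f"bmi_model.{sex}.resid_sd", "must be >= 0")
        _check(0 < bm.lag_coef < 1.2, f"bmi_model.{sex}.lag_coef",
               "must lie in (0, 1.2)")

    for sex in SEXES:
        base = np.asarray(ps.oa_incidence.base_per_1000.get(sex, []), dtype=float)
        _check(base.shape == (N_AGE_BANDS,), f"oa_incidence.base_per_1000.{sex}",
               f"needs {N_AGE_BANDS} age-band values")
        _check(bool(np.all(base >= 0)), f"oa_incidence.base_per_1000.{sex}",
               "rates must be >= 0")
    for cat in BMI_CATEGORIES:
        rr = ps.oa_incidence.rr_bmi.get(cat)
        _check(rr is not None and len(rr) == 2, f"oa_incidence.rr_bmi.{cat}",
               "needs [male, female] relative risks")
        _check(all(r >= 0 for r in rr), f"oa_incidence.rr_bmi.{cat}", "RR must be >= 0")
    _check(ps.oa_incidence.rr_bmi["normal"] == [1.0, 1.0],
           "oa_incidence.rr_bmi.normal", "normal-weight RR must be 1")

    for attr in ATTRIBUTES:
        _check(attr in ps.hui3_models, f"hui3_models.{attr}", "missing attribute")
        m = ps.hui3_models[attr]
        cp = np.asarray(m.cutpoints, dtype=float)
        _check(len(cp) == m.n_levels - 1, f"hui3_models.{attr}.cutpoints",
               "needs n_levels - 1 cutpoints")
        _check(bool(np.all(np.diff(cp) > 0)), f"hui3_models.{attr}.cutpoints",
               "cutpoints must be strictly increasing")
        for c_attr in m.concurrent_coefs:
            _check(c_attr in ATTRIBUTES, f"hui3_models.{attr}.concurrent_coefs",
                   f"unknown attribute {c_attr!r}")
    _check(sorted(ps.hui3_update_order) == sorted(ATTRIBUTES),
           "hui3_update_order", "must be a permutation of the 8 attributes")
    _check(ps.hui3_update_order[-1] == "pain", "hui3_update_order",
           "pain must be updated last")
    order_pos = {a: i for i, a in enumerate(ps.hui3_update_order)}
    for attr in ATTRIBUTES:
        for c_attr in ps.hui3_models[attr].concurrent_coefs:
            _check(order_pos[c_attr] < order_pos[attr],
                   f"hui3_models.{attr}.concurrent_coefs",
                   f"{c_attr!r} is not updated before {attr!r}")

    um = ps.utility_map
    _check(um.constant >= 1.0, "utility_map.constant", "must be >= 1")
    for attr in ATTRIBUTES:
        f = np.asarray(um.factors.get(attr, []), dtype=float)
        _check(f.shape == (ps.hui3_models[attr].n_levels,),
               f"utility_map.factors.{attr}", "one factor per level required")
        _check(f[0] == 1.0, f"utility_map.factors.{attr}",
               "best level factor must be 1")
        _check(bool(np.all(np.diff(f) <= 0)), f"utility_map.factors.{attr}",
               "factors must be nonincreasing in level")

    for drug in DRUGS:
        _check(drug in ps.medications.prevalence, f"medications.prevalence.{drug}",
               "missing drug prevalence table")
        tab = np.asarray(ps.medications.prevalence[drug], dtype=float)
        _check(tab.shape == (2, N_AGE_BANDS, len(OA_STAGES), N_PAIN_LEVELS),
               f"medications.prevalence.{drug}",
               f"table must have shape (2, {N_AGE_BANDS}, 4, 5)")
        _check(bool(np.all((tab >= 0) & (tab <= 1))),
               f"medications.prevalence.{drug}", "prevalences must lie in [0, 1]")
        for fieldname in ("improve_prob", "improve2_prob", "background_nonoa"):
            v = getattr(ps.medications, fieldname).get(drug)
            _check(v is not None, f"medications.{fieldname}.{drug}", "missing drug")
            _check(0 <= v <= 1, f"medications.{fieldname}.{drug}",
                   "must lie in [0, 1]")
        p1 = ps.medications.improve_prob[drug]
        p2 = ps.medications.improve2_prob[drug]
        _check(p1 + p2 <= 1, f"medications.improve_prob.{drug}",
               "improvement probabilities must sum to <= 1")

    se = ps.side_effects
    for drug, r in list(se.gi_excess.items()) + list(se.dyspepsia_rate.items()):
        _check(0 <= r <= 1, f"side_effects.rates.{drug}", "must lie in [0, 1]")
    for nm in ("cvd_baseline", "stroke_baseline"):
        b = np.asarray(getattr(se, nm), dtype=float)
        _check(b.shape == (N_AGE_BANDS,), f"side_effects.{nm}",
               f"needs {N_AGE_BANDS} age-band values")
        _check(bool(np.all((b >= 0) & (b <= 1))), f"side_effects.{nm}",
               "must lie in [0, 1]")
    for drug, rr in list(se.cvd_rr.items()) + list(se.stroke_rr.items()):
        _check(rr >= 0, f"side_effects.rr.{drug}", "RR must be >= 0")
    _check(0 <= se.opioid_overdose_death_prob <= 1,
           "side_effects.opioid_overdose_death_prob", "must lie in [0, 1]")

    tm = ps.treatment_mortality
    for nm in ("gi_cf", "cvd_cf", "stroke_cf", "jrs_periop"):
        _check(0 <= getattr(tm, nm) <= 1, f"treatment_mortality.{nm}",
               "must lie in [0, 1]")

    j = ps.jrs_model
    for attr, ors in j.attr_odds.items():
        _check(attr in ATTRIBUTES, f"jrs_model.attr_odds.{attr}", "unknown attribute")
        _check(len(ors) == ps.hui3_models[attr].n_levels,
               f"jrs_model.attr_odds.{attr}", "one odds ratio per level required")
        _check(all(o > 0 for o in ors), f"jrs_model.attr_odds.{attr}",
               "odds ratios must be > 0")
    pg = np.asarray(j.pain_gain_probs, dtype=float)
    _check(bool(np.all(pg >= 0)) and abs(pg.sum() - 1) < 1e-9,
           "jrs_model.pain_gain_probs", "must be a probability vector")
    _check(0 <= j.mobility_improve_prob <= 1, "jrs_model.mobility_improve_prob",
           "must lie in [0, 1]")
    _check(j.max_primaries == 4, "jrs_model.max_primaries",
           "the model caps primary surgeries at 4")

    for name, entry in ps.parameter_uncertainty.items():
        _check(name in _REGISTRY, f"parameter_uncertainty.{name}",
               "not a registered sensitivity parameter")
        _check(entry["lower95"] <= entry["mean"] <= entry["upper95"],
               f"parameter_uncertainty.{name}", "requires lower95 <= mean <= upper95")


# ---------------------------------------------------------------------------
# File I/O (YAML)
# ---------------------------------------------------------------------------

def save_parameters(ps: ParameterSet, path) -> None:
    """Serialize a ParameterSet to a YAML parameter file."""
    with open(path, "w") as fh:
        yaml.safe_dump(ps.to_dict(), fh, sort_keys=True)


def _from_dict(data: dict) -> ParameterSet:
    def build(cls, d):
        names = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - names
        if extra:
            raise ParameterError(f"{cls.__name__}: unknown keys {sorted(extra)}")
        return cls(**d)

    defaults = build_default_parameters()
    top = {f.name for f in dataclasses.fields(ParameterSet)}
    extra = set(data) - top
    if extra:
        raise ParameterError(f"parameter file: unknown top-level keys {sorted(extra)}")
    for key in top:
        if key not in data:
            logger.info("parameter file omits %r; default used", key)
    kw: dict = {}
    kw["schema_version"] = data.get("schema_version", SCHEMA_VERSION)
    kw["demography"] = (build(Demography, data["demography"])
                        if "demography" in data else defaults.demography)
    if "bmi_model" in data:
        kw["bmi_model"] = {s: build(BmiSexModel, v)
                           for s, v in data["bmi_model"].items()}
    else:
        kw["bmi_model"] = defaults.bmi_model
    kw["oa_incidence"] = (build(OaIncidence, data["oa_incidence"])
                          if "oa_incidence" in data else defaults.oa_incidence)
    if "hui3_models" in data:
        kw["hui3_models"] = {a: build(Hui3AttributeModel, v)
                             for a, v in data["hui3_models"].items()}
    else:
        kw["hui3_models"] = defaults.hui3_models
    for key, cls in (("utility_map", UtilityMap),
                     ("medications", MedicationModel),
                     ("side_effects", SideEffectModel),
                     ("treatment_mortality", TreatmentMortality),
                     ("jrs_model", JrsModel)):
        kw[key] = build(cls, data[key]) if key in data else getattr(defaults, key)
    for key in ("hui3_update_order", "hui3_init", "parameter_uncertainty"):
        kw[key] = data.get(key, getattr(defaults, key))
    return ParameterSet(**kw)


def load_parameters(path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML parameter file.

    Missing optional sections fall back to the synthetic defaults (with a
    logged notice); any invariant violation raises ParameterError naming the
    offending key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParameterError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: parameter file must be a mapping")
    if data.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ParameterError(
            f"schema_version: expected {SCHEMA_VERSION}, "
            f"got {data.get('schema_version')}")
    ps = _from_dict(data)
    validate_parameters(ps)
    return ps


# ---------------------------------------------------------------------------
# Steady-state calibration
# ---------------------------------------------------------------------------

def bmi_category_probs(ps: ParameterSet, sex: str) -> dict:
    """BMI category mass under the sex's initial log-normal BMI distribution."""
    bm = ps.bmi_model[sex]
    mu, sd = bm.init_mean_log, bm.init_sd_log
    edges = np.log([18.5, 25.0, 30.0])
    cdf = norm.cdf((edges - mu) / sd) if sd > 0 else (edges >= mu).astype(float)
    return {"underweight": cdf[0], "normal": cdf[1] - cdf[0],
            "overweight": cdf[2] - cdf[1], "obese": 1 - cdf[2]}


def mean_bmi_rr(ps: ParameterSet, sex: str) -> float:
    """BMI-mixture-averaged OA relative risk for one sex."""
    probs = bmi_category_probs(ps, sex)
    si = SEXES.index(sex)
    return float(sum(probs[c] * ps.oa_incidence.rr_bmi[c][si]
                     for c in BMI_CATEGORIES))


def oa_cumulative_hazard(ps: ParameterSet, sex: str, ages=None,
                         rr: float | None = None) -> np.ndarray:
    """Cumulative OA hazard from age 20 to each age (piecewise-constant bands)."""
    if ages is None:
        ages = AGES
    if rr is None:
        rr = mean_bmi_rr(ps, sex)
    base = np.asarray(ps.oa_incidence.base_per_1000[sex], dtype=float) / 1000.0
    ages = np.asarray(ages, dtype=float)
    cum = np.zeros_like(ages)
    for i, a in enumerate(ages):
        # integral of the band-step hazard over [20, a)
        full = np.arange(20, int(a))
        cum[i] = base[age_band_index(full)].sum() if len(full) else 0.0
        cum[i] += base[age_band_index(int(a))] * (a - int(a))
    return cum * rr


def calibrate_steady_state_prevalence(ps: ParameterSet, demography=None,
                                      ages=None) -> "pd.DataFrame":
    """Initial OA prevalence by age and sex for a stationary epidemic.

    OA is absorbing and carries no direct excess mortality, so at steady state
    the prevalence at age *a* is the incidence accumulated over survivorship:
    ``p(a) = 1 - exp(-H(a))`` with ``H`` the cumulative hazard from age 20,
    using the BMI-mixture-averaged relative risk.  The ``demography`` argument
    (population structure) is accepted so a caller can standardise the result;
    the age profile itself does not depend on it.
    """
    import pandas as pd

    if ages is None:
        ages = AGES
    out = {"age": np.asarray(ages)}
    for sex in SEXES:
        out[sex] = 1.0 - np.exp(-oa_cumulative_hazard(ps, sex, ages=ages))
    df = pd.DataFrame(out)
    if not np.all(np.isfinite(df[list(SEXES)].to_numpy())):
        raise CalibrationError("non-finite prevalence in steady-state calibration")
    return df


# ---------------------------------------------------------------------------
# Rate titration
# ---------------------------------------------------------------------------

def titrate_rate(ps: ParameterSet, target_count: float, observable: Callable,
                 bounds: tuple[float, float] = (0.0, 1.0),
                 tol: float | None = None, max_iter: int = 60) -> float:
    """Find the rate at which ``observable(rate)`` hits ``target_count``.

    ``observable`` maps a candidate rate to an expected annual event count and
    must be monotone nondecreasing (e.g. a fixed-seed simulation of overdose
    deaths).  Bisection; tolerance defaults to max(5% of target, 2 events).
    """
    if target_count < 0:
        raise ValueError("target_count must be >= 0")
    if tol is None:
        tol = max(0.05 * target_count, 2.0)
    if target_count == 0:
        return 0.0
    lo, hi = bounds
    f_lo, f_hi = observable(lo), observable(hi)
    if target_count < f_lo - tol or target_count > f_hi + tol:
        raise TitrationError(
            f"target {target_count} outside achievable range "
            f"[{f_lo}, {f_hi}] for rate bounds {bounds}")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = observable(mid)
        if abs(f_mid - target_count) <= tol:
            return mid
        if f_mid < target_count:
            lo = mid
        else:
            hi = mid
    raise TitrationError(
        f"titration did not converge within {max_iter} iterations")
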