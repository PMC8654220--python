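"""OA onset, OA staging, and the eight-attribute HUI3 health-state machinery.

HUI3 attributes (vision, hearing, speech, mobility, dexterity, emotion,
cognition, pain) are each modelled with ordinal logistic regression under the
proportional-odds assumption.  Attributes are updated one at a time in a fixed
hierarchical order with pain last; each attribute's linear predictor sees its
own lagged level, covariates, comorbidity flags, and the already-updated
concurrent values of earlier attributes.  A multiplicative utility map scores
the resulting 8-level vector on the health-utility scale (1 = full health).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .params import ATTRIBUTES, OaIncidence, ParameterSet, SEXES, age_band_index
from .bmi import bmi_category_index

STAGE_NONE = -1
STAGE_OA_LT5 = 0
STAGE_OA_GE5 = 1
STAGE_POSTJRS_LT5 = 2
STAGE_POSTJRS_GE5 = 3
STAGE_NAMES = {STAGE_NONE: "none", STAGE_OA_LT5: "oa_lt5", STAGE_OA_GE5: "oa_ge5",
               STAGE_POSTJRS_LT5: "postjrs_lt5", STAGE_POSTJRS_GE5: "postjrs_ge5"}
NO_YEAR = -(10**9)  # sentinel for "never"


# ---------------------------------------------------------------------------
# OA incidence
# ---------------------------------------------------------------------------

def oa_hazard(age, sex_idx, bmi, model: OaIncidence) -> np.ndarray:
    """Annual OA onset hazard: base(age band, sex)/1000 x RR(BMI category, sex)."""
    age = np.atleast_1d(np.asarray(age))
    sex_idx = np.broadcast_to(np.atleast_1d(sex_idx), age.shape)
    bmi = np.broadcast_to(np.atleast_1d(np.asarray(bmi, dtype=float)), age.shape)
    base = np.stack([np.asarray(model.base_per_1000[s], dtype=float)
                     for s in SEXES])  # (2, bands)
    rr = np.stack([np.asarray(model.rr_bmi[c], dtype=float)
                   for c in ("underweight", "normal", "overweight", "obese")])
    h = base[sex_idx, age_band_index(age)] / 1000.0
    return h * rr[bmi_category_index(bmi), sex_idx]


def onset_probability(hazard) -> np.ndarray:
    """Annual onset probability from a constant within-year hazard."""
    return 1.0 - np.exp(-np.asarray(hazard, dtype=float))


def sample_oa_onset(age, sex_idx, bmi, model: OaIncidence, u) -> np.ndarray:
    """Bernoulli onset indicator given keyed uniforms ``u``; OA is absorbing,
    so callers apply this only to members without OA."""
    return np.asarray(u) < onset_probability(oa_hazard(age, sex_idx, bmi, model))


def oa_stage(has_oa, oa_onset_year, last_jrs_year, year: int) -> np.ndarray:
    """OA stage codes; post-JRS stages take precedence over OA-duration stages.

    Returns STAGE_NONE for members without OA, otherwise one of
    oa_lt5 / oa_ge5 / postjrs_lt5 / postjrs_ge5 by elapsed time (<5 years).
    """
    has_oa = np.atleast_1d(np.asarray(has_oa, dtype=bool))
    onset = np.broadcast_to(np.atleast_1d(oa_onset_year), has_oa.shape)
    jrs = np.broadcast_to(np.atleast_1d(last_jrs_year), has_oa.shape)
    stage = np.full(has_oa.shape, STAGE_NONE, dtype=np.int64)
    had_jrs = jrs > NO_YEAR
    stage[has_oa & ~had_jrs & (year - onset < 5)] = STAGE_OA_LT5
    stage[has_oa & ~had_jrs & (year - onset >= 5)] = STAGE_OA_GE5
    stage[has_oa & had_jrs & (year - jrs < 5)] = STAGE_POSTJRS_LT5
    stage[has_oa & had_jrs & (year - jrs >= 5)] = STAGE_POSTJRS_GE5
    return stage


# ---------------------------------------------------------------------------
# Proportional-odds machinery
# ---------------------------------------------------------------------------

def ordinal_probs(linear_predictor, cutpoints) -> np.ndarray:
    """Category probabilities of a proportional-odds model.

    ``P(Y <= k) = logistic(cutpoint_k - lp)``; the returned vector has
    ``len(cutpoints) + 1`` entries, nonnegative and summing to 1.  For array
    ``linear_predictor`` the categories live on the last axis.
    """
    cp = np.asarray(cutpoints, dtype=float)
    if cp.ndim != 1 or len(cp) == 0 or np.any(np.diff(cp) <= 0):
        raise ValueError("cutpoints must be a strictly increasing 1-d sequence")
    lp = np.asarray(linear_predictor, dtype=float)
    cdf = expit(cp - lp[..., None])
    full = np.concatenate([np.zeros_like(lp[..., None]), cdf,
                           np.ones_like(lp[..., None])], axis=-1)
    return np.diff(full, axis=-1)


def sample_ordinal(linear_predictor, cutpoints, u) -> np.ndarray:
    """Sample 1-based ordinal levels by inverting the cumulative logistic."""
    cp = np.asarray(cutpoints, dtype=float)
    lp = np.asarray(linear_predictor, dtype=float)
    cdf = expit(cp - lp[..., None])
    return 1 + (np.asarray(u)[..., None] > cdf).sum(axis=-1)


def hui3_linear_predictor(model, lag_level, covars: dict, new_levels: dict):
    """Linear predictor for one attribute given covariates and the
    already-updated concurrent attributes (dict attr -> level array)."""
    lp = (model.lag_coef * (np.asarray(lag_level, dtype=float) - 1.0)
          + model.age_coef * (covars["age"] - 50.0)
          + model.sex_coef * covars["female"]
          + model.year_coef * (covars["year"] - 2020)
          + model.edu_coef * covars["education"]
          + model.income_coef * covars["income"]
          + model.smoking_coef * covars["smoking_current"]
          + model.bmi_coef * (covars["bmi"] - 25.0) / 5.0
          + model.oa_coef * covars["has_oa"]
          + model.postjrs_coef * covars.get("postjrs", 0.0))
    for flag, coef in model.comorb_coefs.items():
        lp = lp + coef * covars["comorb"][flag]
    for attr, coef in model.concurrent_coefs.items():
        lp = lp + coef * (np.asarray(new_levels[attr], dtype=float) - 1.0)
    return lp


def update_hui3(levels: np.ndarray, ps: ParameterSet, covars: dict,
                uniforms_by_attr: dict) -> np.ndarray:
    """Hierarchical annual update of all eight attributes.

    ``levels`` is an (n, 8) array of current 1-based levels in ATTRIBUTES
    order.  Attributes are resampled sequentially in
    ``ps.hui3_update_order`` (pain last); each draw consumes the keyed
    uniform supplied for that attribute in ``uniforms_by_attr``.
    """
    new = levels.copy()
    updated: dict = {}
    for attr in ps.hui3_update_order:
        j = ATTRIBUTES.index(attr)
        model = ps.hui3_models[attr]
        lp = hui3_linear_predictor(model, levels[:, j], covars, updated)
        new[:, j] = sample_ordinal(lp, model.cutpoints, uniforms_by_attr[attr])
        updated[attr] = new[:, j]
    return new


# ---------------------------------------------------------------------------
# Utility scoring and pain effects
# ---------------------------------------------------------------------------

def utility(levels, ps: ParameterSet) -> np.ndarray:
    """Multi-attribute utility of (n, 8) level vectors; all-best scores 1.0."""
    levels = np.atleast_2d(np.asarray(levels, dtype=np.int64))
    if levels.shape[-1] != len(ATTRIBUTES):
        raise ValueError("level vector must have 8 attributes")
    c = ps.utility_map.constant
    prod = np.ones(levels.shape[0])
    for j, attr in enumerate(ATTRIBUTES):
        f = np.asarray(ps.utility_map.factors[attr], dtype=float)
        lv = levels[:, j]
        if np.any((lv < 1) | (lv > len(f))):
            raise ValueError(f"{attr} level out of range 1..{len(f)}")
        prod *= f[lv - 1]
    return c * prod - (c - 1.0)


def sample_pain_improvement(u, improve_prob: float, improve2_prob: float) -> np.ndarray:
    """Integer pain-level improvement (0, 1 or 2) from one drug's annual
    transition distribution (placebo effect included)."""
    u = np.asarray(u)
    return np.where(u < improve2_prob, 2,
                    np.where(u < improve2_prob + improve_prob, 1, 0)).astype(np.int64)


def apply_pain_change(pain, improvement) -> np.ndarray:
    """Decrement pain by the sampled improvement, clamped to levels 1..5."""
    pain = np.asarray(pain, dtype=np.int64)
    return np.clip(pain - np.asarray(improvement, dtype=np.int64), 1, 5)
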