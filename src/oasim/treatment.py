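"""Analgesic use, drug side effects, and joint replacement surgery (JRS).

Medication status is re-sampled every year from point-prevalence tables
(age band x sex x OA stage x pain level); intervention scenarios act on the
*odds* of use.  The four drug classes act independently in both pain
reduction and side effects.  JRS follows a log-linear rate model in age, sex
and calendar year, scaled by an HUI3 attribute-level odds modifier.
"""

from __future__ import annotations

import numpy as np

from .params import ATTRIBUTES, DRUGS, JrsModel, MedicationModel, ParameterSet, \
    SideEffectModel, age_band_index

DRUG_INDEX = {d: i for i, d in enumerate(DRUGS)}


# ---------------------------------------------------------------------------
# Medication use
# ---------------------------------------------------------------------------

def medication_probabilities(model: MedicationModel, age, sex_idx, stage, pain) -> np.ndarray:
    """Point-prevalence lookup for all four drugs.

    Returns an (n, 4) array in DRUGS order for members with OA.  ``stage`` is
    the integer OA stage code 0..3; callers handle non-OA members through the
    configured background table.
    """
    age = np.atleast_1d(np.asarray(age))
    n = age.shape[0]
    sex_idx = np.broadcast_to(np.atleast_1d(sex_idx), (n,))
    stage = np.broadcast_to(np.atleast_1d(stage), (n,))
    pain = np.broadcast_to(np.atleast_1d(pain), (n,))
    band = age_band_index(age)
    out = np.empty((n, len(DRUGS)))
    for j, drug in enumerate(DRUGS):
        tab = np.asarray(model.prevalence[drug], dtype=float)
        out[:, j] = tab[sex_idx, band, stage, pain - 1]
    return out


def apply_odds_multiplier(p, m) -> np.ndarray:
    """Scale the odds of a probability: p' = m*p / (1 - p + m*p).

    Identity at m = 1; fixed points at p = 0 and p = 1 (for m > 0).  The
    degenerate corner p = 1, m = 0 returns 0 by the formula's limit.
    """
    p = np.asarray(p, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p must lie in [0, 1]")
    if np.any(m < 0):
        raise ValueError("multiplier must be >= 0")
    num = m * p
    den = 1.0 - p + num
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def sample_medications(probs, u) -> np.ndarray:
    """Independent Bernoulli use indicators for the four drug classes.

    ``probs`` and ``u`` are (n, 4); co-use of all four drugs is allowed and
    carries no interaction.
    """
    return np.asarray(u) < np.asarray(probs, dtype=float)


# ---------------------------------------------------------------------------
# Side effects
# ---------------------------------------------------------------------------

def combined_excess_rate(meds: np.ndarray, rate_by_drug: dict) -> np.ndarray:
    """1 - prod(1 - r_d) over the drugs a person uses (independent risks)."""
    n = meds.shape[0]
    no_event = np.ones(n)
    for drug, rate in rate_by_drug.items():
        user = meds[:, DRUG_INDEX[drug]]
        no_event = no_event * np.where(user, 1.0 - rate, 1.0)
    return 1.0 - no_event


def excess_vascular_prob(meds: np.ndarray, baseline: np.ndarray, rr_by_drug: dict) -> np.ndarray:
    """Excess annual event probability attributable to drug use.

    Each linked drug contributes an independent excess risk of
    ``baseline * (RR - 1)`` on top of the baseline that everyone faces.
    """
    no_event = np.ones(meds.shape[0])
    for drug, rr in rr_by_drug.items():
        user = meds[:, DRUG_INDEX[drug]]
        excess = np.clip(baseline * max(rr - 1.0, 0.0), 0.0, 1.0)
        no_event = no_event * np.where(user, 1.0 - excess, 1.0)
    return 1.0 - no_event


def vascular_baseline(model: SideEffectModel, which: str, age) -> np.ndarray:
    """Baseline CVD or stroke incidence by age band (all adults)."""
    table = np.asarray(getattr(model, f"{which}_baseline"), dtype=float)
    return table[age_band_index(np.asarray(age))]


def overdose_death_prob(meds: np.ndarray, model: SideEffectModel) -> np.ndarray:
    """Annual overdose death probability: configured value for opioid users,
    exactly 0 otherwise."""
    opioid = meds[:, DRUG_INDEX["opioid"]]
    return np.where(opioid, model.opioid_overdose_death_prob, 0.0)


# ---------------------------------------------------------------------------
# Joint replacement surgery
# ---------------------------------------------------------------------------

def jrs_log_rate(model: JrsModel, which: str, age, female, year) -> np.ndarray:
    """Log-linear (Poisson) rate for primary or revision JRS."""
    prefix = "primary" if which == "primary" else "revision"
    return (getattr(model, f"{prefix}_intercept")
            + getattr(model, f"{prefix}_age_coef") * (np.asarray(age, dtype=float) - model.ref_age)
            + getattr(model, f"{prefix}_female_coef") * np.asarray(female, dtype=float)
            + getattr(model, f"{prefix}_year_coef") * (year - model.ref_year))


def attr_odds_modifier(model: JrsModel, levels: np.ndarray) -> np.ndarray:
    """Raw attribute-level odds modifier: product of per-attribute odds
    ratios at each person's HUI3 levels (1 for attributes not in the model)."""
    mod = np.ones(levels.shape[0])
    for attr, ors in model.attr_odds.items():
        j = ATTRIBUTES.index(attr)
        mod = mod * np.asarray(ors, dtype=float)[levels[:, j] - 1]
    return mod


def jrs_rate(ps: ParameterSet, which: str, age, female, year, levels,
             modifier_norm: float = 1.0) -> np.ndarray:
    """Annual JRS hazard: exp(Poisson log-rate) x normalised attribute modifier.

    ``modifier_norm`` is the fixed population-average raw modifier (computed
    once from the initial OA population) so the marginal rate matches the
    Poisson model's prediction.  Odds ratios multiply the rate directly --
    odds approximate rates for events this rare.
    """
    rate = np.exp(jrs_log_rate(ps.jrs_model, which, age, female, year))
    return rate * attr_odds_modifier(ps.jrs_model, np.atleast_2d(levels)) / modifier_norm


def event_probability(hazard, multiplier=1.0) -> np.ndarray:
    """Annual event probability 1 - exp(-multiplier * hazard)."""
    return 1.0 - np.exp(-np.asarray(multiplier, dtype=float)
                        * np.asarray(hazard, dtype=float))


def sample_jrs_gains(ps: ParameterSet, u_pain, u_mobility) -> tuple[np.ndarray, np.ndarray]:
    """Post-JRS HUI3 improvements: pain falls 0/1/2 levels with the configured
    probabilities; mobility improves one level with its configured probability."""
    pg = np.asarray(ps.jrs_model.pain_gain_probs, dtype=float)
    cdf = np.cumsum(pg)
    pain_gain = np.searchsorted(cdf, np.asarray(u_pain), side="right")
    mobility_gain = (np.asarray(u_mobility) < ps.jrs_model.mobility_improve_prob)
    return pain_gain.astype(np.int64), mobility_gain.astype(np.int64)
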