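"""Annual BMI dynamics: autoregressive log-BMI update and preventive reduction.

BMI evolves on the log scale through a sex-specific AR(1)-style linear model
with demographic covariates and Gaussian noise, then preventive scenarios
subtract a fixed amount per year from everyone at or above the overweight
threshold (eligibility re-checked each year on the post-update value).
"""

from __future__ import annotations

import logging

import numpy as np

from .params import BmiSexModel

logger = logging.getLogger(__name__)

BMI_MIN, BMI_MAX = 12.0, 70.0
OVERWEIGHT_THRESHOLD = 25.0

_CATEGORY_EDGES = np.array([18.5, 25.0, 30.0])
_CATEGORY_NAMES = np.array(["underweight", "normal", "overweight", "obese"])


def linear_predictor(coeffs: BmiSexModel, log_bmi, age, education=0, income=0,
                     region=0, year=2020) -> np.ndarray:
    """Deterministic part of the log-BMI update."""
    return (coeffs.intercept
            + coeffs.lag_coef * np.asarray(log_bmi, dtype=float)
            + coeffs.age_coef * (np.asarray(age, dtype=float) - 50.0)
            + coeffs.year_coef * (year - 2020)
            + coeffs.edu_coef * np.asarray(education, dtype=float)
            + coeffs.income_coef * np.asarray(income, dtype=float)
            + coeffs.region_coef * np.asarray(region, dtype=float))


def update_bmi(bmi, coeffs: BmiSexModel, noise, age, education=0, income=0,
               region=0, year=2020) -> np.ndarray:
    """One annual BMI update: exp(linear predictor + sd * noise), clamped.

    ``noise`` is a standard-normal draw (array-aligned with ``bmi``); passing
    zeros gives the deterministic conditional mean on the log scale.  Values
    are clamped to [12, 70] kg/m^2 with a logged clamp count.
    """
    bmi = np.asarray(bmi, dtype=float)
    lp = linear_predictor(coeffs, np.log(bmi), age, education, income, region, year)
    new = np.exp(lp + coeffs.resid_sd * np.asarray(noise, dtype=float))
    clamped = int(np.sum((new < BMI_MIN) | (new > BMI_MAX)))
    if clamped:
        logger.debug("BMI clamp applied to %d individuals", clamped)
    return np.clip(new, BMI_MIN, BMI_MAX)


def apply_bmi_reduction(bmi, reduction: float) -> np.ndarray:
    """Preventive intervention: subtract ``reduction`` kg/m^2 from everyone with
    BMI >= 25 at the time of application.

    The result may land below 25; eligibility is re-assessed each year, so a
    person drifting back above the threshold re-enters the intervention.
    """
    if reduction < 0:
        raise ValueError("reduction must be >= 0")
    bmi = np.asarray(bmi, dtype=float)
    return np.where(bmi >= OVERWEIGHT_THRESHOLD, bmi - reduction, bmi)


def bmi_category(bmi):
    """WHO-style category: <18.5 underweight, 18.5-24.9 normal, 25.0-29.9
    overweight, >=30.0 obese (half-open boundaries)."""
    idx = bmi_category_index(bmi)
    out = _CATEGORY_NAMES[idx]
    return out.item() if np.isscalar(bmi) else out


def bmi_category_index(bmi) -> np.ndarray:
    """Category as an integer 0..3 (underweight..obese)."""
    bmi = np.asarray(bmi, dtype=float)
    if np.any(bmi <= 0):
        raise ValueError("BMI must be positive")
    return np.searchsorted(_CATEGORY_EDGES, bmi, side="right")
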