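"""OA onset, staging, proportional-odds sampling, utility, pain effects."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from oasim import rng
from oasim.hui3 import (NO_YEAR, apply_pain_change, oa_hazard, oa_stage,
                        onset_probability, ordinal_probs,
                        sample_oa_onset, sample_ordinal,
                        sample_pain_improvement, update_hui3, utility,
                        STAGE_NONE, STAGE_OA_LT5, STAGE_OA_GE5,
                        STAGE_POSTJRS_LT5, STAGE_POSTJRS_GE5)
from oasim.params import ATTRIBUTES


# -- OA hazard / onset -------------------------------------------------------

def test_hazard_is_base_times_rr(params):
    ps = params.copy()
    ps.oa_incidence.base_per_1000 = {"male": [8.1] * 15, "female": [11.1] * 15}
    ps.oa_incidence.rr_bmi = {"underweight": [1, 1], "normal": [1, 1],
                              "overweight": [1, 1], "obese": [2.0, 2.0]}
    # normal-BMI male
    assert oa_hazard(50, 0, 22.0, ps.oa_incidence) == pytest.approx(0.0081)
    # obese male: doubled
    assert oa_hazard(50, 0, 33.0, ps.oa_incidence) == pytest.approx(0.0162)
    # obese female at configured base: hand product
    assert oa_hazard(60, 1, 31.0, ps.oa_incidence) == pytest.approx(0.0111 * 2)


def test_onset_zero_hazard_never_fires(params):
    ps = params.copy()
    ps.oa_incidence.base_per_1000 = {"male": [0.0] * 15, "female": [0.0] * 15}
    u = rng.uniforms(1, 2, 2020, np.arange(1000))
    assert not sample_oa_onset(np.full(1000, 50), np.zeros(1000, int),
                               np.full(1000, 22.0), ps.oa_incidence, u).any()


def test_onset_rate_matches_closed_form(params):
    ps = params.copy()
    ps.oa_incidence.base_per_1000 = {"male": [10.0] * 15, "female": [10.0] * 15}
    ps.oa_incidence.rr_bmi = {c: [1.0, 1.0] for c in
                              ("underweight", "normal", "overweight", "obese")}
    n = 100_000
    u = rng.uniforms(5, 3, 2021, np.arange(n))
    hits = sample_oa_onset(np.full(n, 50), np.zeros(n, int), np.full(n, 22.0),
                           ps.oa_incidence, u).mean()
    p = 1 - np.exp(-0.01)
    assert abs(hits - p) < 3 * np.sqrt(p * (1 - p) / n)


@pytest.mark.parametrize("has_oa,onset,jrs,year,expected", [
    (True, 2018, NO_YEAR, 2020, STAGE_OA_LT5),
    (True, 2010, NO_YEAR, 2020, STAGE_OA_GE5),
    (True, 2000, 2019, 2020, STAGE_POSTJRS_LT5),   # JRS takes precedence
    (True, 2000, 2010, 2020, STAGE_POSTJRS_GE5),
    (False, NO_YEAR, NO_YEAR, 2020, STAGE_NONE),
])
def test_oa_stage(has_oa, onset, jrs, year, expected):
    assert oa_stage(has_oa, onset, jrs, year)[0] == expected


# -- proportional odds -------------------------------------------------------

def test_ordinal_probs_symmetry():
    assert np.allclose(ordinal_probs(0.0, [0.0]), [0.5, 0.5])


def test_ordinal_probs_limit_all_mass_worst():
    p = ordinal_probs(60.0, [-1.0, 0.0, 1.0])
    assert p[-1] == pytest.approx(1.0, abs=1e-12)


def test_ordinal_probs_hand_evaluated():
    lp, cp = 1.0, [-1.0, 0.0, 1.0, 2.0]
    cdf = expit(np.asarray(cp) - lp)
    expected = np.diff(np.concatenate([[0.0], cdf, [1.0]]))
    assert np.allclose(ordinal_probs(lp, cp), expected, atol=1e-15)


def test_ordinal_probs_rejects_nonmonotone():
    with pytest.raises(ValueError):
        ordinal_probs(0.0, [1.0, 0.0])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(lp=st.floats(-30, 30),
       cuts=st.lists(st.floats(-20, 20), min_size=1, max_size=6, unique=True))
def test_ordinal_probs_sum_to_one(lp, cuts):
    p = ordinal_probs(lp, sorted(cuts))
    assert np.all(p >= 0)
    assert abs(p.sum() - 1.0) < 1e-12


def test_sample_ordinal_inverts_cdf():
    cp = [-0.5, 0.7]
    lp = np.zeros(4)
    cdf = expit(np.asarray(cp))
    u = np.array([cdf[0] - 0.01, cdf[0] + 0.01, cdf[1] - 0.01, cdf[1] + 0.01])
    assert sample_ordinal(lp, cp, u).tolist() == [1, 2, 2, 3]


# -- hierarchical update -----------------------------------------------------

def _pin_all_level1(ps):
    out = ps.copy()
    for attr in ATTRIBUTES:
        m = out.hui3_models[attr]
        m.cutpoints = [50.0 + 10.0 * k for k in range(m.n_levels - 1)]
    return out


def test_update_pinned_to_level_one(params, small_pop):
    ps = _pin_all_level1(params)
    n = 50
    levels = np.ones((n, 8), dtype=np.int64)
    covars = {"age": np.full(n, 55.0), "female": np.zeros(n), "year": 2021,
              "education": np.full(n, 2.0), "income": np.full(n, 3.0),
              "smoking_current": np.zeros(n), "bmi": np.full(n, 26.0),
              "has_oa": np.ones(n),
              "comorb": {c: np.zeros(n) for c in
                         ("diabetes", "hypertension", "cvd", "stroke",
                          "ulcer", "dyspepsia")}}
    u = {a: rng.uniforms(1, 70 + j, 2021, np.arange(n))
         for j, a in enumerate(ATTRIBUTES)}
    out = update_hui3(levels, ps, covars, u)
    assert np.all(out == 1)


def test_update_matches_sequential_oracle(params):
    """Independent oracle: evaluate each attribute's linear predictor and
    invert the logistic CDF one person and one attribute at a time."""
    ps = params.copy()
    n = 40
    base = np.ones((n, 8), dtype=np.int64)
    base[:, ATTRIBUTES.index("pain")] = np.arange(n) % 5 + 1
    base[:, ATTRIBUTES.index("mobility")] = np.arange(n) % 3 + 1
    covars = {"age": 40.0 + np.arange(n) % 50, "female": (np.arange(n) % 2).astype(float),
              "year": 2022, "education": np.full(n, 2.0), "income": np.full(n, 3.0),
              "smoking_current": (np.arange(n) % 3 == 0).astype(float),
              "bmi": 22.0 + np.arange(n) % 15, "has_oa": (np.arange(n) % 2).astype(float),
              "comorb": {c: (np.arange(n) % 5 == i).astype(float) for i, c in
                         enumerate(("diabetes", "hypertension", "cvd", "stroke",
                                    "ulcer"))} | {"dyspepsia": np.zeros(n)}}
    u = {a: rng.uniforms(9, 70 + j, 2022, np.arange(n))
         for j, a in enumerate(ATTRIBUTES)}
    got = update_hui3(base, ps, covars, u)

    # oracle: scalar loop
    oracle = base.copy()
    updated = {}
    for attr in ps.hui3_update_order:
        j = ATTRIBUTES.index(attr)
        m = ps.hui3_models[attr]
        for i in range(n):
            lp = (m.lag_coef * (base[i, j] - 1) + m.age_coef * (covars["age"][i] - 50)
                  + m.sex_coef * covars["female"][i] + m.year_coef * 2
                  + m.edu_coef * 2 + m.income_coef * 3
                  + m.smoking_coef * covars["smoking_current"][i]
                  + m.bmi_coef * (covars["bmi"][i] - 25) / 5
                  + m.oa_coef * covars["has_oa"][i]
                  + sum(c * covars["comorb"][f][i] for f, c in m.comorb_coefs.items())
                  + sum(c * (updated[a][i] - 1) for a, c in m.concurrent_coefs.items()))
            cdf = expit(np.asarray(m.cutpoints) - lp)
            oracle[i, j] = 1 + int((u[attr][i] > cdf).sum())
        updated[attr] = oracle[:, j]
    assert np.array_equal(got, oracle)


# -- utility -----------------------------------------------------------------

def test_perfect_health_scores_one(params):
    assert utility(np.ones((1, 8), int), params)[0] == pytest.approx(1.0)


def test_worst_vector_hits_floor(params):
    worst = np.array([[params.hui3_models[a].n_levels for a in ATTRIBUTES]])
    c = params.utility_map.constant
    prod = np.prod([params.utility_map.factors[a][-1] for a in ATTRIBUTES])
    assert utility(worst, params)[0] == pytest.approx(c * prod - (c - 1))
    assert utility(worst, params)[0] >= -(c - 1)


def test_single_deficit_matches_map(params):
    v = np.ones((1, 8), int)
    v[0, ATTRIBUTES.index("pain")] = 3
    c = params.utility_map.constant
    f = params.utility_map.factors["pain"][2]
    assert utility(v, params)[0] == pytest.approx(c * f - (c - 1))


def test_utility_monotone_in_every_attribute(params):
    """Exhaustive over the collapsed grid: worsening any one attribute never
    increases utility."""
    sizes = [params.hui3_models[a].n_levels for a in ATTRIBUTES]
    grid = np.array(list(itertools.product(*[range(1, s + 1) for s in sizes[:4]])))
    # vary the first four attributes exhaustively, fix the rest at level 2
    base = np.ones((len(grid), 8), dtype=int) * 2
    base[:, :4] = grid
    u0 = utility(base, params)
    for j in range(8):
        worse = base.copy()
        cap = sizes[j]
        worse[:, j] = np.minimum(worse[:, j] + 1, cap)
        changed = worse[:, j] != base[:, j]
        assert np.all(utility(worse, params)[changed] <= u0[changed] + 1e-12)


def test_utility_rejects_out_of_range(params):
    bad = np.ones((1, 8), int)
    bad[0, 0] = 99
    with pytest.raises(ValueError):
        utility(bad, params)


# -- pain change -------------------------------------------------------------

def test_degenerate_effect_leaves_pain():
    u = np.linspace(0.01, 0.99, 9)
    gain = sample_pain_improvement(u, 0.0, 0.0)
    assert np.all(gain == 0)
    assert np.array_equal(apply_pain_change(np.full(9, 3), gain), np.full(9, 3))


def test_guaranteed_improvement_clamps_at_one():
    pain = apply_pain_change(np.array([2]), 1)
    assert pain[0] == 1
    assert apply_pain_change(pain, 1)[0] == 1  # clamped


def test_multi_drug_outcome_distribution_matches_convolution(params):
    """Exhaustive enumeration oracle: apply the four drugs' improvement
    distributions in fixed order to pain level 5 and compare the sampled
    outcome distribution with the convolution."""
    probs = {d: (params.medications.improve_prob[d],
                 params.medications.improve2_prob[d])
             for d in ("acetaminophen", "nsaid", "coxib", "opioid")}
    # enumeration over all (g1..g4) in {0,1,2}^4
    dist = np.zeros(6)
    for gains in itertools.product(range(3), repeat=4):
        p = 1.0
        for (d, (p1, p2)), g in zip(probs.items(), gains):
            p *= (p2 if g == 2 else p1 if g == 1 else 1 - p1 - p2)
        final = max(1, 5 - sum(gains))
        dist[final] += p
    n = 200_000
    pain = np.full(n, 5)
    for j, (d, (p1, p2)) in enumerate(probs.items()):
        u = rng.uniforms(3, 80 + j, 2020, np.arange(n))
        pain = apply_pain_change(pain, sample_pain_improvement(u, p1, p2))
    freq = np.bincount(pain, minlength=6) / n
    for k in range(1, 6):
        sd = np.sqrt(max(dist[k] * (1 - dist[k]), 1e-12) / n)
        assert abs(freq[k] - dist[k]) < 4 * sd + 1e-4
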