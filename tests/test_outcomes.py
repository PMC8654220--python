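"""DALY/YLD/YLL/QALY accounting against independent brute-force recomputation."""

import numpy as np
import pandas as pd
import pytest

from oasim import (build_ledger, dalys_averted, disability_weight,
                   effectiveness_ratio, percentage_averted, run_scenarios,
                   total_oa_dalys, yld, yld_table, yll_difference)
from oasim.outcomes import UndefinedWeightError, collapse_strata


def _table(scenario, years, sexes=("male", "female"), seed=0):
    """Random but well-formed person-year tables for accounting tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for year in years:
        for sex in sexes:
            for ag in ("20-69", "70+"):
                pt = rng.uniform(4000, 6000)
                oa = rng.uniform(0.05, 0.3) * pt
                u_oa = rng.uniform(0.6, 0.9)
                u_non = rng.uniform(0.85, 0.99)
                rows.append({"scenario": scenario, "year": year, "sex": sex,
                             "age_group": ag, "person_time": pt,
                             "oa_person_time": oa, "util_pt_oa": u_oa * oa,
                             "util_pt_nonoa": u_non * (pt - oa),
                             "primary_jrs": int(rng.integers(0, 50)),
                             "revision_jrs": int(rng.integers(0, 10)),
                             "deaths_treatment": int(rng.integers(0, 5))})
    return pd.DataFrame(rows)


def test_disability_weight_arithmetic():
    g = pd.DataFrame({"person_time": [1000.0], "oa_person_time": [200.0],
                      "util_pt_oa": [200 * 0.783], "util_pt_nonoa": [800 * 0.85]})
    assert disability_weight(g) == pytest.approx(0.85 - 0.783)


def test_disability_weight_zero_and_negative():
    g = pd.DataFrame({"person_time": [100.0], "oa_person_time": [40.0],
                      "util_pt_oa": [40 * 0.9], "util_pt_nonoa": [60 * 0.9]})
    assert disability_weight(g) == pytest.approx(0.0)
    g["util_pt_oa"] = 40 * 0.95
    assert disability_weight(g) < 0  # allowed, logged


def test_disability_weight_undefined_on_empty_group():
    g = pd.DataFrame({"person_time": [100.0], "oa_person_time": [0.0],
                      "util_pt_oa": [0.0], "util_pt_nonoa": [90.0]})
    with pytest.raises(UndefinedWeightError):
        disability_weight(g)


@pytest.mark.parametrize("prev,dw,pt,expected", [
    (0.1, 0.05, 1000.0, 5.0),
    (0.0, 0.5, 1000.0, 0.0),
    (0.122, 0.067, 12345.0, 0.122 * 0.067 * 12345.0),
])
def test_yld_product(prev, dw, pt, expected):
    assert yld(prev, dw, pt) == pytest.approx(expected)


def test_yll_difference_signs():
    assert yll_difference(10_000.0, 10_000.0) == 0.0
    assert yll_difference(10_050.0, 10_000.0) == 50.0


def test_dalys_averted_prefix_sum_oracle():
    rng = np.random.default_rng(42)
    d_yld = rng.normal(size=20)
    d_yll = rng.normal(size=20)
    annual, cum = dalys_averted(d_yld, d_yll)
    assert np.allclose(annual, d_yld + d_yll)
    # independent prefix-sum oracle
    acc, oracle = 0.0, []
    for v in annual:
        acc += v
        oracle.append(acc)
    assert np.allclose(cum, oracle, atol=1e-12)


def test_effectiveness_ratio_cases():
    assert effectiveness_ratio(100.0, 50.0) == pytest.approx(2.0)
    assert effectiveness_ratio(0.0, 10.0) == 0.0
    assert np.isnan(effectiveness_ratio(5.0, 0.0))


def test_ledger_base_vs_itself_zero():
    base = _table("Base-case", range(2020, 2030))
    led = build_ledger({"Base-case": base})
    sub = led[led.scenario == "Base-case"]
    for col in ("d_yld", "d_yll", "dalys_averted", "cum_dalys_averted",
                "d_qaly", "add_surgeries"):
        assert np.allclose(sub[col], 0.0)


def test_ledger_accounting_identity_random_tables():
    """DALYs averted must equal independently recomputed d_yld + d_yll for
    every (scenario, year, sex) on random person-year tables."""
    for case in range(25):
        base = _table("Base-case", range(2020, 2026), seed=100 + case)
        scen = _table("X", range(2020, 2026), seed=200 + case)
        led = build_ledger({"Base-case": base, "X": scen})
        sub = led[led.scenario == "X"].set_index(["year", "sex"])
        gb = collapse_strata(base).set_index(["year", "sex"])
        gs = collapse_strata(scen).set_index(["year", "sex"])
        for (year, sex), row in sub.iterrows():
            # brute-force recomputation from the raw person-year table
            def _yld(g):
                pt = g.loc[(year, sex), "person_time"]
                oa = g.loc[(year, sex), "oa_person_time"]
                dw = (g.loc[(year, sex), "util_pt_nonoa"] / (pt - oa)
                      - g.loc[(year, sex), "util_pt_oa"] / oa)
                return (oa / pt) * dw * pt
            d_yld = _yld(gb) - _yld(gs)
            d_yll = (gs.loc[(year, sex), "person_time"]
                     - gb.loc[(year, sex), "person_time"])
            assert abs(row["dalys_averted"] - (d_yld + d_yll)) < 1e-9


def test_prevention_scenarios_have_zero_yll():
    base = _table("Base-case", range(2020, 2025))
    scen = _table("BMI-1.0", range(2020, 2025), seed=77)
    led = build_ledger({"Base-case": base, "BMI-1.0": scen})
    sub = led[led.scenario == "BMI-1.0"]
    assert np.allclose(sub["d_yll"], 0.0)
    assert not np.allclose(
        yll_difference(collapse_strata(scen)["person_time"],
                       collapse_strata(base)["person_time"]), 0.0)


def test_total_oa_dalys_suppressed_equals_base_gives_zero_yll():
    base = _table("Base-case", range(2020, 2024), seed=5)
    sup = base.assign(scenario="Suppressed-treatment")
    tot = total_oa_dalys(base, sup)
    assert np.allclose(tot["total_yll"], 0.0)
    assert np.allclose(tot["total_dalys"], tot["total_yld"])
    assert (tot["total_yld"] > 0).all()


def test_total_oa_dalys_hand_computed():
    base = _table("Base-case", [2020], seed=8)
    sup = _table("Suppressed-treatment", [2020], seed=9)
    tot = total_oa_dalys(base, sup).set_index("sex")
    gb = collapse_strata(base).set_index("sex")
    gs = collapse_strata(sup).set_index("sex")
    for sex in ("male", "female"):
        pt, oa = gb.loc[sex, "person_time"], gb.loc[sex, "oa_person_time"]
        dw = (gb.loc[sex, "util_pt_nonoa"] / (pt - oa)
              - gb.loc[sex, "util_pt_oa"] / oa)
        expected = (oa / pt) * dw * pt + (gs.loc[sex, "person_time"] - pt)
        assert tot.loc[sex, "total_dalys"] == pytest.approx(expected)


def test_total_oa_dalys_requires_suppressed_run():
    with pytest.raises(ValueError):
        total_oa_dalys(_table("Base-case", [2020]), None)


def test_percentage_averted_uses_cumulative_ratio():
    base = _table("Base-case", range(2020, 2023), seed=1)
    scen = _table("X", range(2020, 2023), seed=2)
    led = build_ledger({"Base-case": base, "X": scen})
    tot = total_oa_dalys(base, base.assign(scenario="sup"))
    merged = percentage_averted(led, tot)
    sub = merged[(merged.scenario == "X") & (merged.sex == "male")].sort_values("year")
    cum_tot = tot[tot.sex == "male"].sort_values("year")["total_dalys"].cumsum()
    expected = 100 * sub["cum_dalys_averted"].to_numpy() / cum_tot.to_numpy()
    assert np.allclose(sub["pct_total_dalys"], expected)


def test_ledger_person_time_matches_population_conservation(params):
    """End-to-end: ledger person-time equals the engine's person-time exactly."""
    tables = run_scenarios(params, ["Base-case"], n=3000, years=4, seed=2)
    t = tables["Base-case"]
    led = yld_table(t)
    assert np.allclose(led.groupby("year")["person_time"].sum(),
                       t.groupby("year")["person_time"].sum())
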