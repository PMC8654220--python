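"""Scenario definitions, common-random-number coupling, engine invariants."""

import numpy as np
import pandas as pd
import pytest

from oasim import (SCENARIO_NAMES, Scenario, build_scenario,
                   build_suppressed_treatment_scenario, run_scenarios, simulate,
                   initialize_population)
from oasim.scenarios import MedicationModifier

TABLE1 = {
    "Base-case": dict(jrs=1.0, bmi=0.0, med={}),
    "Medication x2": dict(jrs=1.0, bmi=0.0,
                          med={("acetaminophen", 2, (20, 200)): 2.0,
                               ("nsaid", 2, (20, 69)): 2.0,
                               ("nsaid", 3, (70, 200)): 2.0,
                               ("coxib", 2, (20, 69)): 2.0,
                               ("coxib", 3, (70, 200)): 2.0,
                               ("opioid", 3, (20, 200)): 2.0}),
    "Medication x3": dict(jrs=1.0, bmi=0.0,
                          med={("acetaminophen", 2, (20, 200)): 3.0,
                               ("nsaid", 2, (20, 69)): 3.0,
                               ("nsaid", 3, (70, 200)): 3.0,
                               ("coxib", 2, (20, 69)): 3.0,
                               ("coxib", 3, (70, 200)): 3.0,
                               ("opioid", 3, (20, 200)): 3.0}),
    "Surgery x2": dict(jrs=2.0, bmi=0.0, med={}),
    "Surgery x3": dict(jrs=3.0, bmi=0.0, med={}),
    "BMI-0.1": dict(jrs=1.0, bmi=0.1, med={}),
    "BMI-0.3": dict(jrs=1.0, bmi=0.3, med={}),
    "BMI-0.5": dict(jrs=1.0, bmi=0.5, med={}),
    "BMI-1.0": dict(jrs=1.0, bmi=1.0, med={}),
}


@pytest.mark.parametrize("name", SCENARIO_NAMES)
def test_scenario_definitions_match_strategy_table(name):
    sc = build_scenario(name)
    spec = TABLE1[name]
    assert sc.name == name
    assert sc.start_year == 2020
    assert sc.jrs_multiplier == spec["jrs"]
    if spec["jrs"] != 1.0:
        assert sc.jrs_min_pain == 2
    assert sc.bmi_reduction == spec["bmi"]
    if spec["bmi"] > 0:
        assert sc.bmi_threshold == 25.0
    got = {(m.drug, m.min_pain, tuple(m.age_range)): m.multiplier
           for m in sc.medication_modifiers}
    assert got == spec["med"]


def test_unknown_scenario_lists_valid_names():
    with pytest.raises(ValueError, match="Base-case"):
        build_scenario("Medication x9")


def test_invalid_modifier_rejected():
    with pytest.raises(ValueError):
        Scenario(name="bad", jrs_multiplier=0.0)
    with pytest.raises(ValueError):
        Scenario(name="bad", bmi_reduction=-1.0)


def test_null_intervention_is_bit_identical_to_base(params):
    """A scenario whose modifiers are all 1 and reduction 0 must reproduce
    base-case outputs exactly under common random numbers."""
    null = Scenario(name="Null", medication_modifiers=(
        MedicationModifier("nsaid", 1.0, 2, (20, 200)),), jrs_multiplier=1.0)
    tables = run_scenarios(params, [null], n=10_000, years=6, seed=21)
    a = tables["Base-case"].drop(columns="scenario")
    b = tables["Null"].drop(columns="scenario")
    pd.testing.assert_frame_equal(a, b)


def test_base_vs_base_identical(params):
    t = run_scenarios(params, ["Base-case"], n=2000, years=4, seed=3)["Base-case"]
    t2 = run_scenarios(params, ["Base-case"], n=2000, years=4, seed=3)["Base-case"]
    pd.testing.assert_frame_equal(t, t2)


def test_interventions_inactive_before_start_year(params):
    tables = run_scenarios(params, ["Medication x3", "Surgery x3", "BMI-1.0"],
                           n=5000, years=8, seed=13, start_year=2016)
    base = tables["Base-case"]
    for name in ("Medication x3", "Surgery x3", "BMI-1.0"):
        pre = tables[name][tables[name].year < 2020].drop(columns="scenario")
        pd.testing.assert_frame_equal(
            pre, base[base.year < 2020].drop(columns="scenario"))
        post = tables[name][tables[name].year >= 2020]
        assert not post.drop(columns="scenario").equals(
            base[base.year >= 2020].drop(columns="scenario"))


def test_untouched_individuals_identical_across_scenarios(params):
    """CRN coupling: someone no intervention predicate ever touches has an
    exactly equal trajectory in every scenario."""
    init = initialize_population(params, 8000, 2020, seed=17)
    n0 = len(init.ids)
    # step the base-case year by year to record each person's running max BMI
    base = init.copy()
    bmi_max = base.bmi[:n0].copy()
    for _ in range(10):
        simulate(params, build_scenario("Base-case"), base, 1)
        bmi_max = np.maximum(bmi_max, base.bmi[:n0])
    pops = {}
    for name in ("Surgery x3", "BMI-1.0"):
        pop = init.copy()
        simulate(params, build_scenario(name), pop, 10)
        pops[name] = pop
    # Surgery touches only OA members (pain >= 2); OA is absorbing, so people
    # without OA at the end never had it. BMI reduction touches anyone whose
    # BMI ever reached 25.
    never_oa = ~base.has_oa[:n0]
    untouched = {"Surgery x3": never_oa,
                 "BMI-1.0": bmi_max < 25.0}
    for name, other in pops.items():
        common = untouched[name]
        assert common.sum() > 1000
        idx = np.flatnonzero(common)[:500]
        for arr in ("age", "bmi", "alive", "in_pop", "hui3", "pain_base"):
            a = getattr(base, arr)[idx]
            b = getattr(other, arr)[idx]
            assert np.array_equal(a, b), (name, arr)


def test_person_time_accounting_identity(params):
    """Ledger person-time equals the demographic person-time convention
    exactly: survivors 1.0, decedents and emigrants 0.5 in their final year."""
    tables = run_scenarios(params, ["Base-case"], n=5000, years=5, seed=31)
    t = tables["Base-case"]
    g = t.groupby("year")[["person_time", "population", "deaths_background",
                           "deaths_treatment", "emigrants"]].sum()
    expected = (g["population"] + 0.5 * (g["deaths_background"]
                                         + g["deaths_treatment"]
                                         + g["emigrants"]))
    assert np.allclose(g["person_time"], expected)


def test_no_treatment_configured_no_treatment_deaths(params):
    ps = params.copy()
    for d in ps.medications.prevalence:
        ps.medications.prevalence[d] = np.zeros((2, 15, 4, 5)).tolist()
    ps.jrs_model.primary_intercept = -50.0
    ps.jrs_model.revision_intercept = -50.0
    ps.side_effects.cvd_baseline = [0.0] * 15
    ps.side_effects.stroke_baseline = [0.0] * 15
    tables = run_scenarios(ps, ["Base-case"], n=4000, years=6, seed=11)
    t = tables["Base-case"]
    assert int(t["deaths_treatment"].sum()) == 0
    assert int(t[["primary_jrs", "revision_jrs"]].sum().sum()) == 0


def test_suppressed_treatment_scenario_runs_and_differs(params):
    sup = build_suppressed_treatment_scenario()
    tables = run_scenarios(params, [sup], n=5000, years=6, seed=19)
    t = tables["Suppressed-treatment"]
    assert int(t["deaths_treatment"].sum()) == 0
    base = tables["Base-case"]
    # suppressing treatment effects must not reduce person-time
    assert (t.groupby("year").person_time.sum()
            >= base.groupby("year").person_time.sum() - 1e-9).all()


def test_medication_uptake_ordering_under_interventions(params):
    """Year-one drug use among OA rises under Medication x2 and rises further
    under Medication x3, for every drug class."""
    tables = run_scenarios(params, ["Medication x2", "Medication x3"],
                           n=50_000, years=2, seed=23)
    use = {}
    for name, t in tables.items():
        first = t[t.year == 2020]
        use[name] = {d: first[f"users_{d}"].sum() / first["oa_count"].sum()
                     for d in ("acetaminophen", "nsaid", "coxib", "opioid")}
    for d in use["Base-case"]:
        assert use["Medication x2"][d] > use["Base-case"][d], d
        assert use["Medication x3"][d] > use["Medication x2"][d], d


def test_surgery_scenario_adds_surgeries_and_peaks_later(params):
    """Surgical access scenarios perform extra surgeries, and mean HUI3 among
    OA peaks later than under medication scenarios (slower stock effect)."""
    tables = run_scenarios(params, ["Medication x3", "Surgery x3"],
                           n=50_000, years=10, seed=29)

    def series(name):
        t = tables[name]
        g = t.groupby("year")[["util_pt_oa", "oa_person_time"]].sum()
        return g["util_pt_oa"] / g["oa_person_time"]

    base, med, surg = series("Base-case"), series("Medication x3"), series("Surgery x3")
    extra = (tables["Surgery x3"].groupby("year")[["primary_jrs"]].sum()
             - tables["Base-case"].groupby("year")[["primary_jrs"]].sum())
    assert (extra["primary_jrs"] > 0).all()
    gain_med = (med - base)
    gain_surg = (surg - base)
    assert gain_med.idxmax() <= gain_surg.idxmax()


def test_horizon_must_be_positive(params):
    with pytest.raises(ValueError):
        run_scenarios(params, ["Base-case"], n=100, years=0, seed=1)
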