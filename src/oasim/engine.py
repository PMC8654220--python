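"""The annual simulation loop.

Within each simulated year events happen in a fixed, documented order:

1. demographics: aging, background death, emigration, entry (age 20 and
   immigration)
2. autoregressive BMI update
3. preventive-scenario BMI reduction
4. OA incidence (absorbing)
5. medication sampling from point prevalence, with scenario odds modifiers
6. side effects of medication, including lethal opioid overdose
7. JRS sampling (with scenario hazard multiplier), perioperative death, and
   post-surgical HUI3 gains
8. hierarchical HUI3 update (pain last), then same-year drug pain effects
9. accounting snapshot into the person-year table

Treatment responds to the pain level carried into the year; the year's
utility snapshot reflects the year's treatment.  Decedents and emigrants
contribute half a year of person-time at their last known utility.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bmi as bmi_mod
from . import hui3 as hui3_mod
from . import rng
from . import treatment as trt
from .params import ATTRIBUTES, COMORBIDITIES, DRUGS, ParameterSet
from .population import Population, advance_demographics
from .rng import Process
from .scenarios import Scenario

PAIN = ATTRIBUTES.index("pain")
MOBILITY = ATTRIBUTES.index("mobility")
_COMORB_IDX = {c: j for j, c in enumerate(COMORBIDITIES)}
STRATA = [("male", "20-69"), ("male", "70+"), ("female", "20-69"), ("female", "70+")]

EVENT_COLUMNS = ("events_gi", "events_cvd_baseline", "events_cvd_excess",
                 "events_stroke_baseline", "events_stroke_excess",
                 "events_dyspepsia", "deaths_gi", "deaths_cvd", "deaths_stroke",
                 "deaths_overdose", "deaths_periop")


def jrs_modifier_norm(ps: ParameterSet, pop: Population) -> float:
    """Average raw JRS attribute-odds modifier over the initial OA population.

    Used as a fixed normaliser in every scenario so the marginal JRS rate
    matches the Poisson model while common random numbers stay intact."""
    oa = pop.has_oa & pop.active
    if not oa.any():
        return 1.0
    return float(trt.attr_odds_modifier(ps.jrs_model, pop.hui3[oa].astype(np.int64)).mean())


def _medication_matrix(ps: ParameterSet, scenario: Scenario, pop: Population,
                       active_idx: np.ndarray, year: int) -> np.ndarray:
    """Per-person use probabilities for the four drugs, scenario odds applied."""
    n = len(active_idx)
    probs = np.zeros((n, len(DRUGS)))
    has_oa = pop.has_oa[active_idx]
    pain = pop.hui3[active_idx, PAIN].astype(np.int64)
    stage = hui3_mod.oa_stage(has_oa, pop.oa_onset_year[active_idx],
                              pop.last_jrs_year[active_idx], year)
    oa_rows = np.flatnonzero(has_oa)
    if len(oa_rows):
        probs[oa_rows] = trt.medication_probabilities(
            ps.medications, pop.age[active_idx][oa_rows],
            pop.sex[active_idx][oa_rows], stage[oa_rows], pain[oa_rows])
    for j, drug in enumerate(DRUGS):
        bg = ps.medications.background_nonoa[drug]
        if bg > 0:
            probs[~has_oa, j] = bg
    if year >= scenario.start_year:
        age = pop.age[active_idx]
        # eligibility is assessed on the underlying pain state, so treated
        # (masked) severe pain does not leak into mild-pain target groups
        pain_u = pop.pain_base[active_idx].astype(np.int64)
        for mod in scenario.medication_modifiers:
            j = trt.DRUG_INDEX[mod.drug]
            mask = (has_oa & (pain_u >= mod.min_pain) & (pain_u <= mod.max_pain)
                    & (age >= mod.age_range[0]) & (age <= mod.age_range[1]))
            probs[mask, j] = trt.apply_odds_multiplier(probs[mask, j],
                                                       mod.multiplier)
    return probs


def simulate(ps: ParameterSet, scenario: Scenario, pop: Population, years: int,
             collect_events: bool = False) -> pd.DataFrame:
    """Run one scenario for ``years`` annual steps; returns the person-year table.

    ``pop`` must be a scenario-private copy of the shared initial population;
    it is mutated in place.  The table has one row per (year, sex, age group)
    with person-time, OA person-time, utility-weighted person-time by OA
    status, demographic and treatment event tallies, and drug-user counts
    among people with OA.
    """
    seed = pop.seed
    start = pop.calendar_year
    norm = pop.jrs_modifier_norm
    if norm is None:
        norm = jrs_modifier_norm(ps, pop)
    rows: list[dict] = []
    events: list[tuple] = []

    def log_events(ids, year, kind):
        if collect_events and len(ids):
            events.extend((int(i), year, kind) for i in ids)

    for year in range(start, start + years):
        pop.calendar_year = year
        alive_before = pop.alive.copy()
        in_pop_before = pop.in_pop.copy()
        tally = advance_demographics(pop, ps)
        alive_before = np.concatenate(
            [alive_before, np.ones(len(pop) - len(alive_before), dtype=bool)])
        in_pop_before = np.concatenate(
            [in_pop_before, np.ones(len(pop) - len(in_pop_before), dtype=bool)])

        active_idx = np.flatnonzero(pop.active)
        ids = pop.ids[active_idx]
        age = pop.age[active_idx].astype(np.int64)
        sex = pop.sex[active_idx].astype(np.int64)

        # (2) BMI autoregression, by sex
        noise = rng.normals(seed, Process.BMI, year, ids)
        new_bmi = pop.bmi[active_idx].copy()
        for s, sexname in enumerate(("male", "female")):
            m = sex == s
            new_bmi[m] = bmi_mod.update_bmi(
                new_bmi[m], ps.bmi_model[sexname], noise[m], age[m],
                pop.education[active_idx][m], pop.income[active_idx][m],
                pop.region[active_idx][m], year)
        # (3) preventive reduction
        if scenario.bmi_reduction > 0 and year >= scenario.start_year:
            new_bmi = bmi_mod.apply_bmi_reduction(new_bmi, scenario.bmi_reduction)
        pop.bmi[active_idx] = new_bmi

        # (4) OA incidence
        at_risk = active_idx[~pop.has_oa[active_idx]]
        if len(at_risk):
            u = rng.uniforms(seed, Process.OA_ONSET, year, pop.ids[at_risk])
            onset = hui3_mod.sample_oa_onset(
                pop.age[at_risk], pop.sex[at_risk], pop.bmi[at_risk],
                ps.oa_incidence, u)
            newly = at_risk[onset]
            pop.has_oa[newly] = True
            pop.oa_onset_year[newly] = year

        # (5) medication sampling
        probs = _medication_matrix(ps, scenario, pop, active_idx, year)
        u_meds = np.stack([rng.uniforms(seed, Process.MEDICATION + j, year, ids)
                           for j in range(len(DRUGS))], axis=1)
        meds = trt.sample_medications(probs, u_meds)
        pop.meds[:] = False
        pop.meds[active_idx] = meds

        treat_deaths = np.zeros(len(active_idx), dtype=bool)
        counters = {c: np.zeros(len(active_idx), dtype=bool) for c in EVENT_COLUMNS}
        if not scenario.suppress_treatment:
            # (6) side effects
            se, tm = ps.side_effects, ps.treatment_mortality
            gi_p = trt.combined_excess_rate(meds, se.gi_excess)
            gi = rng.uniforms(seed, Process.GI, year, ids) < gi_p
            pop.comorb[active_idx[gi], _COMORB_IDX["ulcer"]] = True
            gi_die = gi & (rng.uniforms(seed, Process.GI_FATAL, year, ids) < tm.gi_cf)
            counters["events_gi"] = gi
            counters["deaths_gi"] = gi_die

            for which, p_ex, p_base, fatal_proc, base_proc, cf in (
                    ("cvd", Process.CVD_EXCESS, Process.CVD, Process.CVD_FATAL,
                     Process.CVD, tm.cvd_cf),
                    ("stroke", Process.STROKE_EXCESS, Process.STROKE,
                     Process.STROKE_FATAL, Process.STROKE, tm.stroke_cf)):
                baseline = trt.vascular_baseline(se, which, age)
                base_ev = rng.uniforms(seed, base_proc, year, ids) < baseline
                ex_p = trt.excess_vascular_prob(meds, baseline,
                                                getattr(se, f"{which}_rr"))
                ex_ev = rng.uniforms(seed, p_ex, year, ids) < ex_p
                pop.comorb[active_idx[base_ev | ex_ev], _COMORB_IDX[which]] = True
                die = ex_ev & (rng.uniforms(seed, fatal_proc, year, ids) < cf)
                counters[f"events_{which}_baseline"] = base_ev
                counters[f"events_{which}_excess"] = ex_ev
                counters[f"deaths_{which}"] = die

            dys_p = trt.combined_excess_rate(meds, se.dyspepsia_rate)
            dys = rng.uniforms(seed, Process.DYSPEPSIA, year, ids) < dys_p
            # non-ulcer dyspepsia is episodic: the flag reflects current-year
            # symptoms and clears when the drug exposure stops
            pop.comorb[active_idx, _COMORB_IDX["dyspepsia"]] = dys
            counters["events_dyspepsia"] = dys

            od_p = trt.overdose_death_prob(meds, se)
            od = rng.uniforms(seed, Process.OVERDOSE, year, ids) < od_p
            counters["deaths_overdose"] = od

            treat_deaths = (counters["deaths_gi"] | counters["deaths_cvd"]
                            | counters["deaths_stroke"] | od)

            # (7) joint replacement surgery
            oa_alive = pop.has_oa[active_idx] & ~treat_deaths
            mult = np.ones(len(active_idx))
            if year >= scenario.start_year and scenario.jrs_multiplier != 1.0:
                pain_now = pop.pain_base[active_idx]
                mult[oa_alive & (pain_now >= scenario.jrs_min_pain)] = \
                    scenario.jrs_multiplier
            levels = pop.hui3[active_idx].astype(np.int64)
            female = sex
            h_primary = trt.jrs_rate(ps, "primary", age, female, year, levels, norm)
            can_primary = oa_alive & (pop.n_primary_jrs[active_idx]
                                      < ps.jrs_model.max_primaries)
            p_primary = np.where(can_primary,
                                 trt.event_probability(h_primary, mult), 0.0)
            primary = rng.uniforms(seed, Process.JRS_PRIMARY, year, ids) < p_primary

            h_rev = trt.jrs_rate(ps, "revision", age, female, year, levels, norm)
            rev_mult = mult if ps.jrs_model.multiplier_applies_to_revision \
                else np.ones_like(mult)
            can_rev = oa_alive & (pop.n_primary_jrs[active_idx] >= 1) & ~primary
            p_rev = np.where(can_rev, trt.event_probability(h_rev, rev_mult), 0.0)
            revision = rng.uniforms(seed, Process.JRS_REVISION, year, ids) < p_rev

            surgery = primary | revision
            periop = surgery & (rng.uniforms(seed, Process.JRS_PERIOP, year, ids)
                                < ps.treatment_mortality.jrs_periop)
            counters["deaths_periop"] = periop
            treat_deaths = treat_deaths | periop
            ok = surgery & ~periop
            rows_ok = active_idx[ok]
            pop.n_primary_jrs[active_idx[primary & ~periop]] += 1
            pop.n_revision_jrs[active_idx[revision & ~periop]] += 1
            pop.last_jrs_year[rows_ok] = year
            if ok.any():
                u_pg = rng.uniforms(seed, Process.JRS_PAIN_GAIN, year, pop.ids[rows_ok])
                u_mg = rng.uniforms(seed, Process.JRS_MOBILITY_GAIN, year,
                                    pop.ids[rows_ok])
                pain_gain, mob_gain = trt.sample_jrs_gains(ps, u_pg, u_mg)
                # surgery acts on the underlying pain state (durable), unlike
                # the annual drug overlay
                pop.pain_base[rows_ok] = np.maximum(
                    1, pop.pain_base[rows_ok] - pain_gain)
                pop.hui3[rows_ok, MOBILITY] = np.maximum(
                    1, pop.hui3[rows_ok, MOBILITY] - mob_gain)
            log_events(pop.ids[active_idx[counters["events_gi"]]], year, "gi")
            log_events(pop.ids[active_idx[counters["events_cvd_excess"]]], year, "cvd")
            log_events(pop.ids[active_idx[counters["events_stroke_excess"]]],
                       year, "stroke")
            log_events(pop.ids[active_idx[counters["events_dyspepsia"]]],
                       year, "dyspepsia")
            log_events(pop.ids[active_idx[od]], year, "overdose_death")
            log_events(pop.ids[active_idx[primary & ~periop]], year, "primary_jrs")
            log_events(pop.ids[active_idx[revision & ~periop]], year, "revision_jrs")
            log_events(pop.ids[active_idx[periop]], year, "periop_death")

            pop.alive[active_idx[treat_deaths]] = False

        # (8) HUI3 hierarchical update for survivors, then drug pain effects
        upd = active_idx[~treat_deaths] if not scenario.suppress_treatment \
            else active_idx
        upd_ids = pop.ids[upd]
        covars = {
            "age": pop.age[upd].astype(float), "female": pop.sex[upd].astype(float),
            "year": year, "education": pop.education[upd].astype(float),
            "income": pop.income[upd].astype(float),
            "smoking_current": (pop.smoking[upd] == 2).astype(float),
            "bmi": pop.bmi[upd], "has_oa": pop.has_oa[upd].astype(float),
            "postjrs": (pop.last_jrs_year[upd] > hui3_mod.NO_YEAR).astype(float),
            "comorb": {c: pop.comorb[upd, j].astype(float)
                       for j, c in enumerate(COMORBIDITIES)},
        }
        u_attr = {attr: rng.uniforms(seed, Process.HUI3 + j, year, upd_ids)
                  for j, attr in enumerate(ATTRIBUTES)}
        levels = pop.hui3[upd].astype(np.int64)
        levels[:, PAIN] = pop.pain_base[upd]  # lag uses the untreated state
        new_levels = hui3_mod.update_hui3(levels, ps, covars, u_attr)
        pop.pain_base[upd] = new_levels[:, PAIN].astype(np.int8)

        if not scenario.suppress_treatment:
            # drug pain relief is an overlay while using: re-applied each
            # treated year on the underlying pain, not compounding
            pain = new_levels[:, PAIN].copy()
            oa_upd = pop.has_oa[upd]
            for j, drug in enumerate(DRUGS):
                user = pop.meds[upd, j] & oa_upd
                if not user.any():
                    continue
                u = rng.uniforms(seed, Process.PAIN_CHANGE + j, year, upd_ids)
                gain = hui3_mod.sample_pain_improvement(
                    u, ps.medications.improve_prob[drug],
                    ps.medications.improve2_prob[drug])
                pain = np.where(user, hui3_mod.apply_pain_change(pain, gain), pain)
            new_levels[:, PAIN] = pain
        pop.hui3[upd] = new_levels.astype(np.int8)

        # (9) accounting snapshot
        died_now = alive_before & ~pop.alive
        emig_now = in_pop_before & ~pop.in_pop & pop.alive
        weight = np.zeros(len(pop))
        weight[pop.active] = 1.0
        weight[died_now | emig_now] = 0.5
        contrib = np.flatnonzero(weight > 0)
        w = weight[contrib]
        util = hui3_mod.utility(pop.hui3[contrib].astype(np.int64), ps)
        strat = (pop.sex[contrib].astype(np.int64) * 2
                 + (pop.age[contrib] >= 70).astype(np.int64))
        oa = pop.has_oa[contrib]
        pt = np.bincount(strat, weights=w, minlength=4)
        oa_pt = np.bincount(strat, weights=w * oa, minlength=4)
        upo = np.bincount(strat, weights=w * util * oa, minlength=4)
        upn = np.bincount(strat, weights=w * util * ~oa, minlength=4)

        strat_a = (pop.sex[active_idx].astype(np.int64) * 2
                   + (pop.age[active_idx] >= 70).astype(np.int64))
        end_active = pop.active[active_idx]
        oa_a = pop.has_oa[active_idx]

        def count_a(mask):
            return np.bincount(strat_a[mask], minlength=4)

        strat_all = (pop.sex.astype(np.int64) * 2 + (pop.age >= 70).astype(np.int64))
        pop_count = np.bincount(strat_all[pop.active], minlength=4)
        oa_count = np.bincount(strat_all[pop.active & pop.has_oa], minlength=4)
        obese_count = np.bincount(strat_all[pop.active & (pop.bmi >= 30.0)],
                                  minlength=4)
        over_count = np.bincount(strat_all[pop.active & (pop.bmi >= 25.0)
                                           & (pop.bmi < 30.0)], minlength=4)
        bg_death = np.bincount(strat_all[died_now & ~_scatter(treat_deaths,
                                                              active_idx, len(pop))],
                               minlength=4)
        tr_death = np.bincount(strat_all[_scatter(treat_deaths, active_idx,
                                                  len(pop))], minlength=4)
        emig_c = np.bincount(strat_all[emig_now], minlength=4)

        users = {d: np.bincount(strat_a[(pop.meds[active_idx, j]) & oa_a
                                        & end_active], minlength=4)
                 for j, d in enumerate(DRUGS)}
        if scenario.suppress_treatment:
            prim_c = np.zeros(4, dtype=int)
            rev_c = np.zeros(4, dtype=int)
            counter_counts = {c: np.zeros(4, dtype=int) for c in EVENT_COLUMNS}
        else:
            prim_c = count_a(primary & ~periop)
            rev_c = count_a(revision & ~periop)
            counter_counts = {c: count_a(counters[c]) for c in EVENT_COLUMNS}

        for k, (sexname, agegrp) in enumerate(STRATA):
            row = {"scenario": scenario.name, "year": year, "sex": sexname,
                   "age_group": agegrp, "person_time": pt[k],
                   "oa_person_time": oa_pt[k], "util_pt_oa": upo[k],
                   "util_pt_nonoa": upn[k], "population": int(pop_count[k]),
                   "oa_count": int(oa_count[k]),
                   "obese": int(obese_count[k]),
                   "overweight": int(over_count[k]),
                   "deaths_background": int(bg_death[k]),
                   "deaths_treatment": int(tr_death[k]),
                   "emigrants": int(emig_c[k]),
                   "entrants": tally["entrants"] if k == 0 else 0,
                   "immigrants": tally["immigrants"] if k == 0 else 0,
                   "primary_jrs": int(prim_c[k]), "revision_jrs": int(rev_c[k])}
            for d in DRUGS:
                row[f"users_{d}"] = int(users[d][k])
            for c in EVENT_COLUMNS:
                row[c] = int(counter_counts[c][k])
            rows.append(row)

    pop.calendar_year = start + years  # next unsimulated year
    table = pd.DataFrame(rows)
    if collect_events:
        # plain tuples: DataFrame-valued attrs break pandas concat
        table.attrs["events"] = events
    return table


def events_frame(table: pd.DataFrame) -> pd.DataFrame:
    """The collected event log of a simulate(..., collect_events=True) table
    as a DataFrame of (id, year, event)."""
    return pd.DataFrame(table.attrs.get("events", []),
                        columns=["id", "year", "event"])


def _scatter(mask_subset: np.ndarray, idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n, dtype=bool)
    out[idx[mask_subset]] = True
    return out
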