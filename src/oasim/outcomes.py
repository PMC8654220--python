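"""Burden accounting: disability weights, YLD/YLL, DALYs averted, QALYs.

Per year and sex, years lived with disability (YLD) are
``OA prevalence rate x disability weight x population person-time`` with the
disability weight the scenario-specific utility gap between people without
and with OA.  YLL differences are person-time differences between a scenario
and the base-case (positive when the scenario extends life); preventive BMI
scenarios contribute zero to OA-related YLLs by construction.  DALYs averted
are the annual sum of the YLD and YLL differences, with an exact running
cumulative.  QALYs are undiscounted utility-weighted person-time.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_KEY = ["year", "sex"]
_SUMS = ["person_time", "oa_person_time", "util_pt_oa", "util_pt_nonoa",
         "primary_jrs", "revision_jrs", "deaths_treatment"]


class UndefinedWeightError(ValueError):
    """Disability weight requested for a group with no OA or no non-OA person-time."""


def collapse_strata(table: pd.DataFrame) -> pd.DataFrame:
    """Sum the person-year table over age groups, keeping (year, sex) rows."""
    return table.groupby(_KEY, as_index=False)[_SUMS].sum()


def disability_weight(group: pd.DataFrame) -> float:
    """Utility gap mean(non-OA) - mean(OA) for one (scenario, year, sex) group.

    A negative weight (OA members reporting higher utility) is allowed and
    logged as an anomaly.
    """
    oa_pt = group["oa_person_time"].sum()
    non_pt = (group["person_time"] - group["oa_person_time"]).sum()
    if len(group) == 0 or oa_pt <= 0 or non_pt <= 0:
        raise UndefinedWeightError(
            "disability weight needs positive OA and non-OA person-time")
    dw = (group["util_pt_nonoa"].sum() / non_pt
          - group["util_pt_oa"].sum() / oa_pt)
    if dw < 0:
        logger.warning("negative disability weight %.4f", dw)
    return float(dw)


def yld(prevalence, dw, person_time) -> float:
    """Years lived with disability: prevalence x weight x person-time."""
    if np.any(np.asarray(prevalence) < 0) or np.any(np.asarray(person_time) < 0):
        raise ValueError("prevalence and person-time must be >= 0")
    return prevalence * dw * person_time


def yld_table(table: pd.DataFrame) -> pd.DataFrame:
    """Annual YLD per (year, sex) from a person-year table (crude prevalence)."""
    g = collapse_strata(table)
    non_pt = g["person_time"] - g["oa_person_time"]
    dw = (g["util_pt_nonoa"] / non_pt.where(non_pt > 0)
          - g["util_pt_oa"] / g["oa_person_time"].where(g["oa_person_time"] > 0))
    prevalence = g["oa_person_time"] / g["person_time"].where(g["person_time"] > 0)
    out = g[_KEY].copy()
    out["disability_weight"] = dw.fillna(0.0)
    out["prevalence"] = prevalence.fillna(0.0)
    out["person_time"] = g["person_time"]
    out["yld"] = yld(out["prevalence"], out["disability_weight"], out["person_time"])
    out["qalys"] = g["util_pt_oa"] + g["util_pt_nonoa"]
    out["surgeries"] = g["primary_jrs"] + g["revision_jrs"]
    return out


def yll_difference(pt_scenario, pt_base) -> np.ndarray:
    """Signed person-time difference; positive when the scenario extends life."""
    return np.asarray(pt_scenario, dtype=float) - np.asarray(pt_base, dtype=float)


def dalys_averted(d_yld, d_yll) -> tuple[np.ndarray, np.ndarray]:
    """Annual DALYs averted (sum of differences) and exact running cumulative."""
    annual = np.asarray(d_yld, dtype=float) + np.asarray(d_yll, dtype=float)
    return annual, np.cumsum(annual)


def effectiveness_ratio(d_qaly, d_surgeries):
    """QALYs gained per additional surgery; NaN where the denominator is 0."""
    d_qaly = np.asarray(d_qaly, dtype=float)
    d_surg = np.asarray(d_surgeries, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(d_surg != 0, d_qaly / np.where(d_surg != 0, d_surg, 1.0),
                       np.nan)
    return out if out.ndim else float(out)


def build_ledger(tables: dict, base_name: str = "Base-case",
                 prevention_scenarios=None) -> pd.DataFrame:
    """Per-(scenario, year, sex) burden ledger of every scenario vs base-case.

    Columns: yld, d_yld, d_yll, dalys_averted, cum_dalys_averted, qalys,
    d_qaly, cum_d_qaly, add_surgeries, cum_add_surgeries, eff_ratio.
    Preventive scenarios (detected by name prefix ``BMI-`` unless given
    explicitly) are assigned zero OA-related YLL differences.
    """
    if base_name not in tables:
        raise KeyError(f"base-case table {base_name!r} required")
    if prevention_scenarios is None:
        prevention_scenarios = {n for n in tables if n.startswith("BMI-")}
    base = yld_table(tables[base_name]).set_index(_KEY)
    ledgers = []
    for name, table in tables.items():
        scen = yld_table(table).set_index(_KEY)
        scen, base_a = scen.align(base, join="inner")
        out = scen.reset_index()[_KEY].copy()
        out.insert(0, "scenario", name)
        out["yld"] = scen["yld"].to_numpy()
        out["d_yld"] = (base_a["yld"] - scen["yld"]).to_numpy()
        d_yll = yll_difference(scen["person_time"], base_a["person_time"])
        if name in prevention_scenarios:
            d_yll = np.zeros_like(d_yll)
        out["d_yll"] = d_yll
        out["qalys"] = scen["qalys"].to_numpy()
        out["d_qaly"] = (scen["qalys"] - base_a["qalys"]).to_numpy()
        out["add_surgeries"] = (scen["surgeries"] - base_a["surgeries"]).to_numpy()
        parts = []
        for sex, sub in out.groupby("sex", sort=False):
            sub = sub.sort_values("year").copy()
            annual, cum = dalys_averted(sub["d_yld"], sub["d_yll"])
            sub["dalys_averted"] = annual
            sub["cum_dalys_averted"] = cum
            sub["cum_d_qaly"] = np.cumsum(sub["d_qaly"])
            sub["cum_add_surgeries"] = np.cumsum(sub["add_surgeries"])
            sub["eff_ratio"] = effectiveness_ratio(sub["cum_d_qaly"],
                                                   sub["cum_add_surgeries"])
            parts.append(sub)
        ledgers.append(pd.concat(parts))
    return pd.concat(ledgers, ignore_index=True)


def total_oa_dalys(base_table: pd.DataFrame,
                   suppressed_table: pd.DataFrame) -> pd.DataFrame:
    """Total annual OA burden: base-case YLD plus OA-related YLLs, the latter
    the person-time gap between the suppressed-treatment counterfactual and
    the base-case (treatment-attributable deaths are the model's only
    OA-related mortality pathway)."""
    if suppressed_table is None:
        raise ValueError("a suppressed-treatment run is required")
    base = yld_table(base_table).set_index(_KEY)
    sup = collapse_strata(suppressed_table).set_index(_KEY)
    idx = base.index.intersection(sup.index)
    base_a, sup = base.loc[idx], sup.loc[idx]
    out = base_a.reset_index()[_KEY].copy()
    out["total_yld"] = base_a["yld"].to_numpy()
    out["total_yll"] = yll_difference(sup["person_time"], base_a["person_time"])
    out["total_dalys"] = out["total_yld"] + out["total_yll"]
    return out


def percentage_averted(ledger: pd.DataFrame, totals: pd.DataFrame) -> pd.DataFrame:
    """Cumulative DALYs averted as % of cumulative total OA DALYs to each year."""
    tot = totals.sort_values(_KEY).copy()
    tot["cum_total"] = tot.groupby("sex")["total_dalys"].cumsum()
    merged = ledger.merge(tot[_KEY + ["cum_total"]], on=_KEY, how="left")
    merged["pct_total_dalys"] = 100.0 * merged["cum_dalys_averted"] / merged["cum_total"]
    return merged
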