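"""One-way sensitivity analysis over the registered parameter uncertainty.

Each registered parameter is set in turn to the mean, lower and upper limit
of its 95% confidence interval while everything else stays fixed; the model
runs the base-case plus one scenario per strategy under common random
numbers, and the impact is summarised as average QALYs per initial person.
Results are ordered by tornado range (largest impact first).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import ParameterSet, perturb_parameter, registered_parameters
from .scenarios import build_scenario
from .engine import simulate
from .population import initialize_population
from .outcomes import collapse_strata

DEFAULT_SCENARIOS = ("Base-case", "Medication x3", "Surgery x3", "BMI-0.5")


def _mean_qaly_per_person(table: pd.DataFrame, n: int) -> float:
    g = collapse_strata(table)
    return float((g["util_pt_oa"] + g["util_pt_nonoa"]).sum() / n)


def run_one_way(ps: ParameterSet, scenario_names=DEFAULT_SCENARIOS,
                n: int = 2000, years: int = 20, seed: int = 1,
                start_year: int = 2020) -> pd.DataFrame:
    """One-way sensitivity table: one row per (parameter, value, scenario).

    ``delta_qaly`` is the change in mean QALYs per initial person relative to
    the same scenario at the parameter's mean; the mean rows are exactly 0 by
    construction.  ``mc_se`` is a rough Monte Carlo standard error of the
    mean QALY estimate (annual person-time variability).  Rows are sorted so
    parameters with the widest tornado range come first.
    """
    names = registered_parameters(ps)
    for name in names:
        entry = ps.parameter_uncertainty[name]
        if not (np.isfinite(entry["lower95"]) and np.isfinite(entry["upper95"])):
            raise ValueError(f"parameter {name!r} lacks finite uncertainty bounds")
    scenarios = [build_scenario(s, start_year) for s in scenario_names]
    init = initialize_population(ps, n, start_year, seed)

    def run(params):
        out = {}
        for sc in scenarios:
            table = simulate(params, sc, init.copy(), years)
            out[sc.name] = (_mean_qaly_per_person(table, n), table)
        return out

    mean_results = run(ps)
    rows = []
    for name in names:
        for which in ("mean", "lower", "upper"):
            if which == "mean":
                results = mean_results
            else:
                results = run(perturb_parameter(ps, name, which))
            q_base = results.get("Base-case", (np.nan, None))[0]
            for sc_name, (q, table) in results.items():
                g = collapse_strata(table)
                annual = (g.groupby("year")[["util_pt_oa", "util_pt_nonoa"]]
                          .sum().sum(axis=1) / n)
                mc_se = float(annual.std(ddof=1) / np.sqrt(max(len(annual), 2)))
                rows.append({"parameter": name, "which": which,
                             "scenario": sc_name, "mean_qaly_per_person": q,
                             "delta_qaly": q - mean_results[sc_name][0],
                             # intervention effect at this parameter value;
                             # common random numbers cancel population-level
                             # influences, isolating interaction with the
                             # scenario
                             "effect_vs_base": q - q_base,
                             "mc_se": mc_se})
    df = pd.DataFrame(rows)
    spread = (df.groupby("parameter")["mean_qaly_per_person"]
              .agg(lambda s: s.max() - s.min()).rename("tornado_range"))
    df = df.merge(spread, on="parameter")
    return (df.sort_values(["tornado_range", "parameter", "scenario", "which"],
                           ascending=[False, True, True, True])
            .reset_index(drop=True))


def tornado_ranges(result: pd.DataFrame, scenario: str,
                   column: str = "mean_qaly_per_person") -> pd.DataFrame:
    """Per-parameter range of ``column`` within one scenario (tornado bar
    lengths).  Use ``column="effect_vs_base"`` to rank parameters by their
    influence on the intervention's effect rather than on the QALY level."""
    sub = result[result["scenario"] == scenario]
    g = sub.groupby("parameter")[column].agg(low="min", high="max")
    g["range"] = g["high"] - g["low"]
    return g.sort_values("range", ascending=False).reset_index()
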