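"""Simulate the base-case (no intervention) and describe the population.

Prints the kind of descriptive table a burden-of-disease projection starts
from: OA prevalence, analgesic use among people with OA, joint replacement
rates, and mean health utility (HUI3) among people with OA.
"""

import oasim

ps = oasim.build_default_parameters(1)
tables = oasim.run_scenarios(ps, ["Base-case"], n=20_000, years=21, seed=1)
t = tables["Base-case"]

for year in (2020, 2040):
    g = (t[t.year == year].groupby("sex")
         [["population", "oa_count", "oa_person_time", "util_pt_oa",
           "primary_jrs"]].sum())
    print(f"--- {year} ---")
    for sex in ("male", "female"):
        r = g.loc[sex]
        print(f"{sex:>6}: OA prevalence {100 * r.oa_count / r.population:.1f}%, "
              f"mean HUI3 (OA) {r.util_pt_oa / r.oa_person_time:.3f}, "
              f"primary JRS {1000 * r.primary_jrs / r.oa_person_time:.0f}/1000 OA p-y")
# Prevalence and surgery rates rise over time (aging population, rising BMI);
# mean utility among OA drifts down as the OA pool ages.

g = t[t.year == 2020].groupby("sex")[[f"users_{d}" for d in oasim.DRUGS]
                                     + ["oa_count"]].sum()
print("analgesic use among OA in 2020 (%):")
for d in oasim.DRUGS:
    male = 100 * g.loc["male", f"users_{d}"] / g.loc["male", "oa_count"]
    female = 100 * g.loc["female", f"users_{d}"] / g.loc["female", "oa_count"]
    print(f"  {d:<14} male {male:4.1f}  female {female:4.1f}")
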