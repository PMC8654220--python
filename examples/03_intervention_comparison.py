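"""Compare intervention strategies as cumulative OA DALYs averted.

Runs the base-case plus one scenario from each strategy family under common
random numbers and prints cumulative DALYs averted at two horizons.
Medication acts immediately (a jump in analgesic coverage); surgery builds a
durable stock of improved post-surgical patients; prevention (BMI reduction)
compounds slowly through avoided OA incidence.
"""

import oasim

ps = oasim.build_default_parameters(1)
names = ["Medication x3", "Surgery x3", "BMI-1.0"]
tables = oasim.run_scenarios(ps, names, n=30_000, years=41, seed=1)
ledger = oasim.build_ledger(tables)

cum = (ledger.groupby(["scenario", "year"])["cum_dalys_averted"].sum()
       .unstack("scenario"))
for year in (2030, 2060):
    print(f"cumulative DALYs averted by {year} "
          f"(simulated population of 30k):")
    for name in names:
        print(f"  {name:<14} {cum.loc[year, name]:8.0f}")
# Expected shape: medication leads over the first decade, surgery overtakes
# in the medium term, and the strong preventive scenario wins over several
# decades. Values scale with the simulated population size.
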