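"""Why the medication scenarios are targeted: subgroup benefit/harm analysis.

Doubles the odds of use of one drug in one (age, pain) cell at a time and
reports the QALY change vs base-case within that age group.  Negative values
mean the drug's side effects outweigh pain relief for that subgroup, which
is exactly why the uptake scenarios exclude those cells.
"""

import oasim

ps = oasim.build_default_parameters(1)
cells = [
    ("opioid", 2, (20, 200), (2, 2)),   # mild pain: overdose risk dominates
    ("opioid", 2, (20, 200), (3, 5)),   # moderate+ pain: net benefit
    ("nsaid", 2, (70, 200), (2, 2)),    # old age + mild pain: vascular/GI harm
    ("nsaid", 2, (20, 69), (2, 5)),     # younger: net benefit
]
df = oasim.preliminary_subgroup_analysis(ps, cells, n=40_000, years=15, seed=1)
for _, r in df.iterrows():
    verdict = "HARM" if r.delta_qaly < 0 else "benefit"
    print(f"{r.drug:<8} x{r.multiplier:.0f} ages {r.age_lo}-{r.age_hi} "
          f"pain {r.pain_lo}-{r.pain_hi}: dQALY {r.delta_qaly:+8.1f}  ({verdict})")
# dQALY is the total QALY difference vs base-case accumulated in the cell's
# age group; signs, not magnitudes, drive the targeting decision.
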