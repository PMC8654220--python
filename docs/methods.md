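# Methods

`oasim` is a discrete-time, open-population microsimulation of osteoarthritis
(OA) burden. It simulates individual life and health histories — BMI, OA
onset, eight-attribute HUI3 health-related quality of life, analgesic use
with side effects, and joint replacement surgery (JRS) — for a base-case and
counterfactual intervention scenarios, and accounts the differences as
OA-related DALYs averted. This note documents the model, its assumptions,
the synthetic default parameter set, the numerical choices, and what the
tests do and do not establish.

## Population and time

Time advances in annual steps. The population is open: people enter by
turning 20 or immigrating and leave by death or emigration; entry counts are
exogenous fractions of the initial population size. Every simulated person
carries demographics (sex, age, education, income, region, smoking), BMI,
OA status with onset year, an 8-level HUI3 state, current analgesic use (4
drug classes), six comorbidity flags, and a surgical history (up to 4
primary JRS, any number of revisions).

Within a year, events happen in a fixed order: (1) demographics — aging,
background death from an age/sex/year table multiplied by comorbidity
relative risks, emigration, entry; (2) the autoregressive BMI update; (3)
preventive-scenario BMI reduction; (4) OA incidence; (5) medication
sampling; (6) medication side effects including lethal opioid overdose; (7)
JRS with perioperative mortality and post-surgical improvements; (8) the
hierarchical HUI3 update with same-year drug pain effects; (9) the
accounting snapshot. Treatment therefore responds to the pain level carried
into the year, and the year's utility reflects the year's treatment.
Decedents and emigrants contribute 0.5 years of person-time in their final
year, at their last known utility (midpoint convention).

## Common random numbers

Every stochastic decision is a pure function of (master seed, process code,
calendar year, person id), generated by a splitmix64-style counter-based
hash rather than sequential generator state. Scenario runs that share a
seed therefore give each person an identical stream of background
randomness: a person never touched by an intervention predicate has a
bit-identical trajectory in every scenario, and between-scenario differences
(DALYs averted) are driven by the interventions, not Monte Carlo noise.
This realises per-(individual, process) substreams with a stateless
mechanism that also vectorises cleanly.

## BMI

Log-BMI follows a sex-specific AR(1)-style model with covariate terms and
Gaussian noise, clamped to [12, 70] kg/m². Defaults place the stationary
distribution near a log-normal with male mean BMI ≈ 26.8 (sd of log 0.16)
and female mean ≈ 25.1 (sd of log 0.20), giving obesity prevalence in the
mid-20s of percent, and a small positive calendar-time term makes obesity
drift upward over decades. The coefficients are interpreted per year; the
survey models behind such parameters are typically estimated on a 2-year
cadence, so this is a documented reinterpretation. Preventive scenarios
subtract a fixed reduction (0.1–1.0 kg/m² per year) after the stochastic
update from everyone at BMI ≥ 25; eligibility is re-assessed annually on the
post-update value, so a person can leave and re-enter the intervention.

## OA incidence and steady-state calibration

The OA onset hazard is a base rate per 1000 person-years by 5-year age band
(half-open [a, a+5), top band 90+) and sex, multiplied by a BMI-category
relative risk (normal weight ≡ 1; defaults: overweight 1.6, obese 2.5,
underweight 0.9). Onset is sampled as 1 − exp(−hazard); OA is absorbing.

Initial prevalence is calibrated so the epidemic is stationary at the start
of the simulation: since OA is absorbing and carries no direct excess
mortality, steady-state prevalence at age a is the incidence accumulated
over survivorship, p(a) = 1 − exp(−H(a)) with H the cumulative band hazard
from age 20 using the BMI-mixture-averaged relative risk. The acceptance
suite verifies (i) agreement with a 10×-finer cohort-accumulation oracle to
1e-3 and (ii) age-standardised prevalence drift below 0.5 percentage points
over the first five simulated years. Residual drift comes from the BMI
secular trend and from BMI–OA correlation building up after the initially
independent assignment; both are second-order.

## HUI3 and utility

Each of the eight HUI3 attributes (vision, hearing, speech, mobility,
dexterity, emotion, cognition, pain) follows an ordinal logistic
(proportional-odds) model: P(level ≤ k) = logistic(cutpoint_k − lp).
Attributes are updated one at a time in a fixed hierarchical order —
vision, hearing, speech, cognition, emotion, mobility, dexterity, pain —
each model seeing its own lagged level, covariates, comorbidity flags, and
the already-updated concurrent values of earlier attributes. Pain is last
so treatment in the same year can act on it; the order is configurable but
pain-last is enforced. Non-pain attributes are collapsed to 3 levels; pain
keeps 5 (no pain … severe pain preventing most activities).

Utility is a configurable multiplicative multi-attribute map,
u = c·∏ f_a(level) − (c − 1) with c = 1.36, each attribute's factors
starting at 1 and nonincreasing. The all-best vector scores exactly 1, the
floor is bounded by −0.36, and worsening any single attribute can never
raise utility (tested exhaustively). The map is a stand-in consistent with
the published HUI3 multiplicative form collapsed to this level structure,
not a re-derivation of the HUI3 scoring coefficients.

### Pain: underlying state vs drug overlay

Pain is carried as two quantities. The *underlying* pain state evolves
through the proportional-odds model and is permanently shifted by surgery
(see below). Analgesics act as a *non-compounding annual overlay*: while a
person uses a drug, a sampled integer improvement (placebo-inclusive; 0, 1
or 2 levels, clamped at level 1) is subtracted from the underlying pain to
give the reported pain that year. Reported pain drives utility, the
medication point-prevalence lookup and the JRS attribute odds; the next
year's pain update lags on the underlying state, so drug benefit persists
only while the drug is used. This separation was a deliberate design
choice: letting drug improvements feed the autoregressive lag makes annual
re-treatment ratchet everyone to the pain floor, which both inflates the
benefit of treating mild pain and makes medication dominate surgery over
every horizon — inverting the medication-fast / surgery-medium /
prevention-long-run structure this class of model exhibits.

Intervention eligibility (the pain ≥ k predicates of the uptake and surgery
scenarios) is assessed on the *underlying* pain: otherwise severe-but-masked
pain leaks into "mild pain" target groups and reverses their benefit/harm
sign. Substantively this treats targeting as based on clinical assessment
of the untreated condition.

## Medication and side effects

Use of acetaminophen, NSAIDs, coxibs and opioids is re-sampled every year
from point-prevalence tables over age band × sex × OA stage (OA <5 y, OA
≥5 y, post-JRS <5 y, post-JRS ≥5 y) × reported pain level; there is no
adherence state, so cross-sectional use is reproduced by construction. The
four drugs are independent in use, pain effect and side effects; co-use is
allowed. Scenario modifiers multiply the *odds* of use,
p′ = m·p / (1 − p + m·p).

Side effects per user-year: serious GI bleeding at an excess rate among
NSAID/coxib/opioid users (sets a persistent ulcer flag; case fatality
0.12); CVD and stroke from an age-banded baseline faced by everyone, with
independent *excess* probability baseline×(RR − 1) for linked users —
persistent flags, case fatalities 0.15/0.20, with only excess-event deaths
counted as treatment-attributable; episodic dyspepsia (the flag reflects
current-year symptoms and clears when exposure stops — non-ulcer dyspepsia
is clinically reversible, and a persistent flag would accumulate unbounded
harm against a flow-only benefit); and lethal opioid overdose at 0.007 per
user-year, a probability designed to be titratable against an observed
national death count (`titrate_rate`, bisection, tolerance max(5%, 2
events)). Persistent flags feed the HUI3 models and multiply background
mortality.

The default effect sizes and harms were chosen so that targeted uptake is
beneficial on average exactly in the groups the scenarios target, and
harmful outside them: increased NSAID/coxib use harms people 70+ with mild
(level 2) pain through vascular and GI risk, and increased opioid use harms
anyone with mild pain through overdose mortality. The subgroup analysis
(`preliminary_subgroup_analysis`) reproduces this sign pattern and is the
basis of the scenario targeting.

## Joint replacement surgery

Primary and revision JRS rates are log-linear in age, sex and calendar year
(defaults tuned so primary rates among OA are ≈45/1000 person-years in 2020,
rising ≈20% by 2040, male slightly above female; revisions ≈4/1000). The
rate is scaled by a product of per-attribute odds ratios at the person's
HUI3 levels (pain dominates: OR 0.5 at no pain up to 5 at severe pain),
normalised by a constant computed once from the initial OA population so
the marginal rate matches the log-linear model. Odds ratios multiply the
rate directly — for events this rare, odds ≈ rates. Normalising against
the *current* population each year would let intervention effects leak into
untouched persons' hazards and break the common-random-number coupling, so
the normaliser is fixed and shared across scenarios.

Primaries are capped at 4 per person; revisions require a prior primary; at
most one surgery per person-year. Each surgery carries perioperative
mortality (0.005). Survivors draw an immediate improvement in underlying
pain (0/1/2 levels) and mobility, and their post-JRS state permanently
lowers the pain model's linear predictor (−0.65), so the surgical benefit is
durable — this is what makes surgery slower than medication over the first
decade (its stock of improved patients builds up with the operated fraction)
but larger over medium horizons. Scenario hazard multipliers apply to
primaries in people with OA and underlying pain ≥ 2; whether revisions also
receive the multiplier is a configurable flag, off by default.

## Outcomes

Per (year, sex): disability weight DW = mean utility among non-OA minus
mean utility among OA (scenario-specific, recomputed each year; negative
values allowed and logged); YLD = crude OA prevalence × DW × person-time;
YLL difference = scenario person-time − base-case person-time (preventive
BMI scenarios are assigned 0 OA-related YLL by construction); DALYs averted
= ΔYLD + ΔYLL with an exact running cumulative. QALYs are undiscounted
utility-weighted person-time; the effectiveness ratio is cumulative ΔQALY
per cumulative additional surgery (undefined cells marked NaN, not raised).
Total OA DALYs (the denominator for percentage-averted reporting) add
base-case YLD to the person-time gap between a suppressed-treatment
counterfactual (all drug and surgery effects off) and the base-case,
treatment-attributable death being the model's only OA-related mortality
channel. Crude (not age-standardised) prevalence is used in YLD; ledgers
are reported per sex with combined totals derivable by summation.

## Scenarios

Nine named scenarios: Base-case; Medication ×2/×3 (odds of use multiplied
in the targeted groups: acetaminophen pain ≥2 all ages, NSAIDs/coxibs pain
≥2 at ages 20–69 and pain ≥3 at 70+, opioids pain ≥3); Surgery ×2/×3 (JRS
hazard multiplied for OA with pain ≥2); BMI−0.1/−0.3/−0.5/−1.0 (annual BMI
reduction for everyone at BMI ≥25). Interventions start in 2020 at full
strength (an implementation ramp is deliberately out of scope). All
scenarios share one initial population and the keyed random streams.

## Synthetic default parameters

No individual-level survey or administrative data are distributable for
this model class, so the default `ParameterSet` is synthetic but
structure-complete, constructed to resemble published Canadian OA figures
in order of magnitude: adult OA prevalence ≈13%/17% (male/female) rising
over two decades, population-average incidence ≈9–12 per 1000 at-risk
person-years, 70+ population share ≈13% rising with aging, NSAID use among
OA ≈35–40% with acetaminophen ≈17/24%, coxibs and opioids ≈4–6%, primary
JRS ≈45/1000 OA person-years, mean HUI3 among OA ≈0.87 and a disability
weight near 0.07–0.1. Every coefficient is overridable through the YAML
parameter file (schema version 1); the sensitivity registry ships 17 named
parameters (BMI→OA relative risks, four drug pain effects, three GI excess
rates, four vascular relative risks, overdose mortality, JRS pain and
mobility improvement, perioperative mortality) with 95% CIs, exportable as
CSV.

What the generator does *not* emulate: real survey joint distributions
(covariates are drawn from independent marginals), joint-specific OA,
adherence and treatment persistence, waiting lists, costs, topical NSAIDs
and exercise therapy, measurement error in self-reported BMI, and
uncertainty in demographic projections. Passing tests therefore establish
internal consistency and the qualitative comparative-dynamics structure,
not Canadian calibration.

## Numerical choices and problem sizes

Bisection titration tolerance is max(5% of target, 2 events). Probability
vectors are validated to 1e-6; proportional-odds probabilities sum to 1 to
1e-12 by construction. Ordinal sampling inverts the cumulative logistic
with a single keyed uniform per attribute-year. The test suite runs the
long-horizon comparison at 100k individuals over 80 years and the subgroup
sign checks at 150k over 20 years — sizes chosen as the smallest at which
the orderings and signs are stable under common random numbers; desk-scale
sensitivity analysis defaults to 2,000 individuals with a Monte Carlo
standard-error column (the rough annual-variability estimate, not a formal
CI). The sensitivity table carries both the QALY level and the intervention
effect (scenario minus base-case at the same parameter value); tornado
rankings of parameter influence on a *scenario* use the effect column, where
common random numbers cancel population-level levers (otherwise broad
exposures such as NSAID vascular risk dominate every scenario's QALY level
and mask the scenario-specific uncertainties). The acceptance script uses
50k individuals over 2020–2100.

## Known limitations

Annual discretisation slightly biases event interactions (a person cannot
die of background causes and then experience a treatment event in the same
year, by construction of the within-year order). Baseline CVD/stroke events
set comorbidity flags without separate baseline-event mortality (background
mortality already absorbs it), so only excess events kill — a deliberate
split that keeps "treatment-attributable deaths" exactly zero when no drugs
are configured. Immigrants receive fresh covariate draws (their health-state
assignment is otherwise unspecified). The preliminary subgroup analysis
reports totals, not per-capita values, and its Monte Carlo noise scales with
the number of people an intervention touches.
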