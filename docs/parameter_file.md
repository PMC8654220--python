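# Parameter file schema (version 1)

The parameter file is YAML, produced by `oasim synth-params` or
`oasim.save_parameters` and read by `oasim.load_parameters`. Any omitted
section falls back to the synthetic defaults (a notice is logged); every
value is validated on load and violations raise an error naming the
offending key. Top-level key `schema_version` must equal `1`.

| key | content |
|---|---|
| `demography` | `entry_rate`, `immigration_rate`, `emigration_rate` (fractions/probabilities per year); `mortality` — per sex, 81 annual death probabilities for ages 20–100; `mortality_year_factor` (annual multiplier); `comorbidity_mortality_rr` — per flag; `age_pyramid` — 81 weights; `sex_split`; `education_probs` (4), `income_probs` (5), `region_probs` (5), `smoking_probs` (3); `immigrant_age_range`; `comorbidity_init` — per flag `[prob at 50, slope/yr]` |
| `bmi_model` | per sex: `intercept`, `lag_coef` ∈ (0, 1.2), `age_coef`, `year_coef`, `edu_coef`, `income_coef`, `region_coef`, `resid_sd` ≥ 0 (log scale), `init_mean_log`, `init_sd_log` |
| `oa_incidence` | `base_per_1000` — per sex, 15 five-year age-band rates; `rr_bmi` — per BMI category `[male, female]` relative risks, `normal` must be `[1, 1]` |
| `hui3_models` | per attribute: `n_levels`, strictly increasing `cutpoints` (`n_levels − 1`), coefficients `lag_coef`, `age_coef`, `sex_coef`, `year_coef`, `edu_coef`, `income_coef`, `smoking_coef`, `bmi_coef`, `oa_coef`, `postjrs_coef`, `comorb_coefs` (map), `concurrent_coefs` (map; keys must be updated earlier in the order) |
| `hui3_update_order` | permutation of the 8 attributes, pain last |
| `hui3_init` | per attribute, level-probability vectors for the four groups `oa_young`, `oa_old`, `nonoa_young`, `nonoa_old` |
| `utility_map` | `constant` ≥ 1 and per-attribute `factors` (one per level, starting at 1, nonincreasing) |
| `medications` | `prevalence` — per drug, nested list of shape (2 sexes × 15 age bands × 4 OA stages × 5 pain levels), all in [0, 1]; `background_nonoa`, `improve_prob`, `improve2_prob` — per drug |
| `side_effects` | `gi_excess`, `dyspepsia_rate` (per drug); `cvd_baseline`, `stroke_baseline` (15 age-band rates); `cvd_rr`, `stroke_rr` (per drug); `opioid_overdose_death_prob` |
| `treatment_mortality` | `gi_cf`, `cvd_cf`, `stroke_cf`, `jrs_periop` case fatalities |
| `jrs_model` | log-linear coefficients for primary and revision (`*_intercept`, `*_age_coef`, `*_female_coef`, `*_year_coef`), `ref_age`, `ref_year`, `attr_odds` (per attribute, one odds ratio per level), `pain_gain_probs` (3-vector), `mobility_improve_prob`, `max_primaries` (= 4), `multiplier_applies_to_revision` |
| `parameter_uncertainty` | per registered sensitivity parameter: `mean`, `lower95`, `upper95`, `units` with `lower95 ≤ mean ≤ upper95` |

Ages are integer years; age bands are half-open five-year bands [a, a+5)
from 20 with a 90+ top band. Pain has 5 levels; other attributes default to
3. The sensitivity registry (names and bounds) can be exported with
`oasim synth-params --registry-csv`.
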