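# Data dictionary

## `visits.csv` — one row per attended woman-visit

| column | type | description |
| --- | --- | --- |
| `woman_id` | int | participant identifier |
| `visit` | int | wave index (0-based protocol visit number) |
| `time_years` | float | years since baseline (jittered around the wave schedule) |
| `age` | float | age in years at the visit |
| `months_since_menses` | float | reported months since last menstrual bleeding |
| `menses_predictable` | bool | menses as predictable as usual (distinguishes premenopause from early perimenopause) |
| `fine_stage` | str | `premenopausal`, `early_peri`, `late_peri`, `early_post`, `late_post` |
| `stage` | int | combined MT stage: 1 = pre/early peri, 2 = late peri/early post, 3 = late post |
| `crp` | float | CRP in mg/L; NaN at visits where CRP was not assayed |
| `ht` | int | hormone-therapy use at the visit (0/1) |
| `bmd_ls`, `bmd_fn` | float | lumbar-spine / femoral-neck BMD in g/cm²; NaN if not measured |
| `bmi` | float | body-mass index, kg/m²; NaN if missing |
| `smoking`, `diabetes` | int | current cigarette use / diabetes (0/1) |
| `alcohol` | int | 0 = abstinent, 1 = infrequent, 2 = light-moderate, 3 = heavy |
| `bone_beneficial`, `bone_adverse` | int | bone-beneficial / bone-adverse medication use (0/1) |
| `corticosteroids`, `nsaids`, `aspirin` | int | medication use (0/1) |
| `calcium`, `vitd` | int | supplement use (0/1) |

## `flags.csv` — one row per assayed woman-visit

`woman_id`, `visit`, `acute_flag` (bool), `step` (`none`/`step1`/`step2`/
`step3`), `comparator` (mg/L, the comparator of the step that fired),
`multiplier` (the *f* used).  Comparator and multiplier are NaN on
unflagged rows.

## `obs_<SITE>.csv` — one row per qualifying exposure observation

`woman_id`, `site` (LS/FN), `visit1`/`visit2` (wave indices of the pair),
`t1`/`t2`/`delta_t` (years; 1.5 ≤ `delta_t` ≤ 3.5), `log2_crp` (exposure at
the first visit, log₂ mg/L), `bmd_t1`/`bmd_t2` (g/cm²), `slope`
(annualized percent BMD change, %/y), `stage` (combined stage at the first
visit) and the covariates at the first visit (same coding as `visits.csv`).

## `waterfall_<SITE>.json`

`n_visits` (censored visit rows), `n_crp_visits` (candidate first visits
with a CRP assay), `excluded_acute`, `excluded_missing_covariate`,
`excluded_missing_bmd`, `excluded_no_partner`, `n_observations` (these five
sum to `n_crp_visits`), then `n_women_pre_filter`, `n_observations_final`
and `n_women_final` after the ≥2-observations rule.

## `ground_truth.json`

Per-woman realized `stage2_entry_time`/`stage3_entry_time` (years, NaN if
never reached), the spike-free chronic log₂ CRP path at every scheduled
assay wave, injected spike locations and factors, and the configured
`beta_per_doubling` tuples for both sites.
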