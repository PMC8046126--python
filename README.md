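# crpbmd

Within-woman analysis of C-reactive protein (CRP) and subsequent bone loss
across the menopause transition (MT).

Chronic low-grade inflammation is a suspected driver of postmenopausal bone
loss, but cross-sectional CRP–BMD comparisons are confounded by everything
that differs *between* women.  `crpbmd` implements, as a tested and reusable
pipeline, a longitudinal design that asks the sharper question: when a
woman's own CRP rises, does her bone mineral density (BMD) decline faster
over the following ~2 years — and does the answer depend on where she is in
the menopause transition?  It is aimed at biostatisticians and
epidemiologists working with repeated-measures cohort data (long-format
per-visit CSV), and ships a seeded synthetic cohort generator so every step
can be exercised and validated against known ground truth without access to
restricted cohort data.

## What it does

1. **Acute-inflammation flagging** (`crpbmd.acute`).  CRP spikes from acute
   illness must not be used as exposures, but an absolute cut-point
   (≥10 mg/L) discards chronically high, stable values.  The
   individual-specific rule compares each woman's largest values against a
   comparator from her *own* series using a multiplier

   *f*(c) = 6 for c ≤ 1; 6/√c for 1 < c < 9; 2 for c ≥ 9   (c in mg/L),

   through a three-step hierarchy (3rd max vs trimmed mean → flags the three
   maxima; 2nd max vs 3rd max → flags two; max vs 2nd max → flags one).

2. **MT staging** (`crpbmd.staging`).  Menstrual histories are coded into
   fine stages (premenopause … late postmenopause) and collapsed to the
   3-level analysis staging: 1 = pre/early perimenopause, 2 = late
   peri/early postmenopause, 3 = late postmenopause.

3. **Exposure periods** (`crpbmd.exposure`).  Each qualifying visit (non-
   acute CRP, BMD, covariates; hormone-therapy use censors) is paired with
   the earliest visit 1.5–3.5 years later with a BMD at the same site.  The
   outcome is the annualized percent BMD change ("slope", %/y); the
   exposure is log₂ CRP at the first visit.

4. **Individual fixed-effects (IFE) regression** (`crpbmd.ife`).  For woman
   *i*, observation *t*:

   slopeᵢₜ = β·log₂CRPᵢₜ + γ′zᵢₜ + αᵢ + εᵢₜ

   estimated by within-transformation (every variable demeaned per woman),
   which removes all time-fixed confounding.  β is the change in BMD slope
   (%/y) *per within-woman doubling of CRP*.  Inference uses Huber-White
   standard errors clustered by woman with CR1 small-sample scaling and
   within-estimator degrees of freedom (equals least-squares-dummy-variable
   estimation exactly).  Nested covariate sets, stage×CRP interaction Wald
   tests, pairwise stage contrasts and stage-stratified fits mirror the
   analysis plan.

5. **Synthetic cohorts** (`crpbmd.cohort`).  A seeded generator emulating
   17 ~annual waves: MT stage progression from menstrual codes,
   between/within-woman log₂ CRP dynamics with multiplicative acute spikes,
   stage-specific BMD decline plus a configurable CRP effect, measurement
   noise, HT initiation and covariate dynamics — with ground truth returned
   for parameter-recovery tests.

## Worked example

`python examples/04_fit_ife.py` simulates 1431 women (the generator's
default scale), builds lumbar-spine exposure observations and fits the
fully adjusted models:

```
lumbar spine: 7961 observations, 1306 women (true stage-wise betas (0.0, 0.0, -0.1))

stage x CRP interaction: Wald chi2(2) = 100.0, p = 1.9e-22 -> the effect differs by MT stage

fully adjusted stage-stratified estimates (%/y per CRP doubling):
  stage 1: beta = +0.005 (-0.053, +0.063), p = 0.863  [3539 obs, 1103 women]
  stage 2: beta = -0.007 (-0.111, +0.097), p = 0.894  [1981 obs, 861 women]
  stage 3: beta = -0.130 (-0.217, -0.043), p = 0.004  [1694 obs, 610 women]
```

Reading: in late postmenopause each within-woman doubling of CRP predicts
about 0.1 %/y faster lumbar-spine BMD loss over the following ~2 years —
the estimator recovers the configured truth (−0.10, inside the CI) — while
in stages 1–2, where the configured effect is zero, the estimates sit near
zero.  The other examples (`examples/01…05`) each exercise one capability
and print a short interpretation; `examples/05_full_pipeline.py` writes the
complete artifact set (flags, observations, fits, Table-style summaries and
a derivation waterfall).

The same pipeline is available from the shell:

```bash
crpbmd run-all --seed 51 --out out/          # or: simulate / classify / build / fit / report
```

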