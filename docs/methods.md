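# Methods

This note documents the statistical machinery, the synthetic-data model and
the numerical/design choices in `crpbmd`.

## The estimand and the IFE estimator

The scientific question is within-woman: when a woman's CRP rises relative
to her own usual level, does her subsequent rate of BMD change worsen?  The
outcome for observation *t* of woman *i* is the annualized percent change
in BMD over a 1.5–3.5-year window starting at the visit where CRP was
measured,

    slope_it = 100 * (BMD_t2 - BMD_t1) / BMD_t1 / (t2 - t1)   [%/y],

and the model is

    slope_it = beta * log2CRP_it + gamma' z_it + alpha_i + eps_it.

`alpha_i` absorbs every time-fixed characteristic (measured or not), so the
estimator uses only within-woman contrasts; with a base-2 log exposure,
`beta` is the %/y change in slope per within-woman *doubling* of CRP.
Estimation demeans every variable by woman and runs OLS on the demeaned
data.  Key numerical/inference choices:

* **Cluster-robust covariance.**  Huber-White sandwich clustered by woman
  with CR1 scaling `G/(G-1) * (N-1)/(N-K)`, where `K = k + G` counts the
  absorbed woman means.  With this convention the within fit equals
  least-squares-dummy-variables (LSDV) estimation coefficient-for-
  coefficient and SE-for-SE (verified against statsmodels LSDV to 1e-8 in
  the tests).  At cohort-like cluster sizes (~6 observations per woman) the
  `(N-1)/(N-K)` factor is ≈ 6/5, which makes the tests mildly
  *conservative* (empirical size of the interaction Wald test ≈ 0.03–0.04
  at nominal 0.05).
* **Reference distribution.**  Normal (z) by default — CIs are
  `estimate ± 1.96 SE` — with a documented toggle (`ci_reference="t"`) for
  a t reference with G−1 degrees of freedom.
* **Degenerate columns.**  Columns with within-woman variance < 1e-12
  (time-fixed) are dropped with a warning, as are collinear columns
  (greedy left-to-right Gram-Schmidt screen after a rank check); dropped
  names are reported on the fit.  A model needing more parameters than
  observations raises.
* **Stratified fits** re-demean within the stratum subsample (a stratified
  IFE model is an IFE model on the subsample) and drop women with fewer
  than two observations *in the stratum* — a singleton contributes only a
  zero row after demeaning but would distort the df accounting.
* **Interaction machinery.**  Stage-specific effects are
  `beta + interaction_s`; the omnibus test is a joint Wald chi-square
  (df 2) on the two interaction coefficients using the robust covariance;
  pairwise stage contrasts are linear contrasts with robust SEs.
* **Covariate coding.**  MT stage enters as 2 indicators (reference:
  stage 1), alcohol as 3 indicators (reference: abstinent); model 1 = stage,
  BMI, smoking, diabetes, alcohol; model 2 adds bone-beneficial and
  bone-adverse medications, oral corticosteroids, NSAIDs and aspirin;
  model 3 adds supplemental calcium and vitamin D.

Descriptive stage comparisons (mean within-woman change in log₂ CRP and in
slope, by the follow-up observation's stage) use a cell-means regression on
stage indicators with woman-clustered robust SEs, giving both per-stage
tests against zero and pairwise stage differences.

## Acute-inflammation classifier

The multiplier is continuous and non-increasing in the comparator
(6 at c ≤ 1, 6/√c between, 2 at c ≥ 9).  Each step evaluates *f* at its own
comparator (trimmed mean, 3rd max, 2nd max respectively); all comparisons
are strict.  Steps whose comparator is undefined are skipped: the trimmed
mean needs ≥ 4 values, a 3rd maximum needs ≥ 3, a 2nd maximum needs ≥ 2; a
single-value series is never flagged.  Ties among maxima are positions in
a stable descending sort, so equal values cannot trigger the strict
inequalities.  Classification uses a woman's entire CRP series across all
study visits (the rule looks at previous *and future* measurements), before
any exposure-period filtering or HT censoring.  Because *f* depends on the
absolute comparator, flags are deliberately not scale-equivariant —
multiplying a series by a constant can create or remove flags (pinned by a
regression test).

## MT staging

Fine stages from months-since-last-menses (msl) and a predictability flag:
premenopause (msl < 3, predictable), early perimenopause (msl < 3, less
predictable), late perimenopause (3 ≤ msl < 12), early postmenopause from
the first visit with msl ≥ 12 (the identification visit), late
postmenopause beginning `early_post_span` *attended* visits after the
identification visit.  The default span is 2 (identification visit plus
one), matching "late postmenopause starts two visits after the visit at
which menopause was identified"; a span of 3 ("the first three
postmenopausal visits") is available as a toggle — the two readings differ
by one visit and both are represented rather than guessed between.  Stages
are ratcheted (never regress within a woman), which also absorbs
physiologically noisy codes just after the final menstrual period.

## Exposure-period construction

Pairing is earliest-subsequent within the 1.5–3.5-year window, which under
~annual visits with occasional misses yields a median gap of ~2.0 years
(IQR ≈ 1.9–2.1).  Overlapping pairs are allowed (a visit can close one pair
and open the next).  An acute-flagged CRP disqualifies a visit only as a
pair's *first* visit; its BMD may still close an earlier pair.  The LS and
FN observation sets are built independently (their missingness differs).
HT censoring removes visits from the first on-HT visit onward and removes
baseline HT users entirely.  Women with fewer than two qualifying
observations per site are dropped (within-woman change is undefined for
them).  Every exclusion is tallied; candidate CRP visits reconcile exactly
with observations plus skip reasons, and the pipeline emits this waterfall
as JSON.

## Synthetic cohort: what it emulates

Defaults describe a 1431-woman cohort observed over 17 ~annual waves.
Per woman:

* **Timeline.**  Entry age ~ U(42, 52); visit *v* at `v ± jitter` years
  (sd 0.08 y); post-baseline visits missed independently with p = 0.10.
  Late-perimenopause onset ~ Normal(5.5, 3.0) years truncated at −2 (so
  ~97% of women enter in stage 1), followed by a truncated-Normal(1.5,
  0.75²) run-in to the final menstrual period.  Menstrual codes are emitted
  per visit and the *analysis staging rule itself* is applied to them, so
  the stages driving the bone model are exactly the stages the pipeline
  reconstructs (round-trip consistency by construction).
* **CRP (log₂ mg/L).**  Between-woman level ~ Normal(0.53, 2.07²); a
  chronic within-woman AR(1) deviation (stationary sd 0.93, lag-1
  correlation 0.3 across assay occasions) sampled at assay visits and held
  constant between them; small per-wave drift by stage (0.02, 0.02, 0
  log₂/wave).  CRP is assayed every second wave by default: the emulated
  study measured CRP at a subset of waves (≈7 assays per woman on average),
  and a biennial schedule reproduces that sparsity while aligning assays
  with the ~2-year exposure windows.  With probability 0.03 an assay is an
  acute spike: the *observed* CRP is multiplied by a factor drawn
  log-uniformly from 6–40×; spikes do not enter the bone model.
* **BMD (g/cm²).**  Baselines ~ Normal(1.07, 0.14²) at the lumbar spine
  and Normal(0.84, 0.13²) at the femoral neck.  True BMD declines
  geometrically between waves at
  `stage_decline[stage] + beta_per_doubling[stage] * log2CRP_chronic`
  percent per year, with stage-specific declines (−0.61, −1.61, −0.65) %/y
  (LS) and (−0.45, −1.28, −0.95) %/y (FN) and CRP effects (0, 0, −0.10)
  (LS) and (−0.09, 0, −0.09) (FN) %/y per doubling.  `log2CRP_chronic` is
  the spike-free value at the most recent assay, so the exposure measured
  at a pair's first visit is the value that actually drives decline over
  the paired interval — the lagged design is correctly specified by
  construction.  Observed BMD multiplies the true value by log-normal
  noise with sd equal to the short-term in-vivo CV (1.4% LS, 2.2% FN);
  BMDs are missing with p = 0.02.
* **HT and covariates.**  HT initiation hazard 0.02/visit (absorbing);
  BMI ~ Normal(27.4, 6.8²) with drift 0.16/y (sd 0.6/visit); binary
  covariates (smoking, diabetes, five medication classes, calcium,
  vitamin D) start at the cohort's baseline prevalences and switch with
  per-visit on/off hazards; alcohol (4 categories) re-draws with p = 0.08;
  BMI is missing with p = 0.01 to exercise the covariate-completeness rule.

Everything is drawn from a single `numpy.random.default_rng(seed)` in fixed
order: generation is bit-reproducible, and the pipeline's artifacts are
byte-identical across reruns with the same seed.

**What it does not emulate:** assay-platform changes and cross-calibration
chemistry (absorbed into measurement noise), DXA hardware cross-calibration
and phantom QC, site/ethnicity structure in CRP, covariate effects on bone
(covariates exist to exercise adjustment, not to confound — the IFE
estimator removes time-fixed confounding regardless), and informative
missingness.  Passing recovery tests therefore demonstrate the *pipeline's*
correctness under the stated generative model, not robustness to every
artifact of real cohort data.

## Validation studies in the test suite

Problem sizes were chosen to give each check real statistical teeth while
keeping the default suite around four minutes:

* Classifier vs a brute-force sort-index-compare oracle on 10,000 random
  series (≤ 12 values); multiplier continuity/monotonicity on a dense grid.
* Within-estimator vs two independent oracles on 1,000 random small panels
  (statsmodels LSDV with cluster covariance; an explicit per-cluster score
  loop), agreement to 1e-8 relative; shift invariance; time-fixed drops.
* Parameter recovery: 200 seeded 500-woman cohorts; the fully adjusted
  stage-3 lumbar-spine estimate averages within 0.02 of the configured
  −0.10 %/y per doubling and its 95% CI covers the truth 90–98% of the
  time.
* Interaction-test calibration: size over 2,000 null panels (300 women,
  3 observations per stage — every woman informs each stage slope) within
  [0.03, 0.07]; power > 0.8 at 1,000-woman cohorts against the configured
  stage-difference alternative.
* Pipeline determinism (byte-identical artifacts) and exact waterfall
  reconciliation.

## Known limitations

* **Boundary attenuation.**  A pair's outcome window can cross a stage
  boundary (the second BMD falls in the next stage), so stratified
  estimates for non-absorbing stages mix in the next stage's effect:
  with the default truth, stage-1 femoral-neck estimates attenuate
  ~25–30% toward zero.  Stage 3 is absorbing, so the headline stage-3
  estimates are clean.
* **Undetected spikes.**  ~¼ of injected spikes (mostly low-factor ones)
  evade the hierarchy and act as exposure measurement error, attenuating
  stage-3 estimates by ~10–15% of the effect (≈ 0.01–0.02 %/y here); this
  mirrors the real design, which also cannot catch every acute elevation.
* **Conservative inference.**  The LSDV-consistent df correction makes
  cluster-robust tests slightly conservative at ~6 observations per woman
  (size ≈ 0.03–0.04 at nominal 0.05).
* The simulator's CRP process (piecewise-constant AR(1) chronic component)
  is one defensible choice; within-woman CRP autocorrelation is not pinned
  down by the emulated study, and the drift/noise/persistence knobs are
  exposed rather than asserted as facts.
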