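"""Individual fixed-effects estimation of the CRP -> BMD-slope association.

The within transform removes every time-fixed confounder; the coefficient
on log2 CRP is the change in annualized BMD slope (%/y) per within-woman
doubling of CRP.  Stage-stratified fits show the effect is concentrated in
late postmenopause (the generator's truth here is -0.10 %/y per doubling in
stage 3, 0 elsewhere at the lumbar spine).
"""

import warnings

from crpbmd import (
    CohortConfig, ModelSpec, build_observations, censor_at_ht, classify_cohort,
    filter_min_two, fit_ife, generate_cohort, wald_interaction_test,
)

warnings.filterwarnings("ignore", message="dropping")

cfg = CohortConfig(n_women=1431, seed=41)
visits, truth = generate_cohort(cfg)
flags = classify_cohort(visits)
obs = filter_min_two(build_observations(censor_at_ht(visits), flags, "LS")[0])
print(f"lumbar spine: {len(obs)} observations, {obs['woman_id'].nunique()} women "
      f"(true stage-wise betas {truth.beta_per_doubling_ls})")

inter = fit_ife(obs, ModelSpec(covariate_set="model3", interaction_with_stage=True))
wald = wald_interaction_test(inter)
print(f"\nstage x CRP interaction: Wald chi2(2) = {wald['statistic']:.1f}, "
      f"p = {wald['p']:.2g} -> the effect differs by MT stage")

print("\nfully adjusted stage-stratified estimates (%/y per CRP doubling):")
for stratum in (1, 2, 3):
    fit = fit_ife(obs, ModelSpec(covariate_set="model3", stratum=stratum))
    print(f"  stage {stratum}: beta = {fit.beta:+.3f} "
          f"({fit.ci_low['log2_crp']:+.3f}, {fit.ci_high['log2_crp']:+.3f}), "
          f"p = {fit.pvalues['log2_crp']:.3f}  "
          f"[{fit.n_obs} obs, {fit.n_women} women]")
print("\nA negative beta means each doubling of CRP predicts that much faster "
      "annual BMD loss over the following ~2 years.")
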