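"""Generate a seeded synthetic cohort and summarize it.

The generator emulates a midlife women's cohort followed across the
menopause transition: ~annual visits, CRP assayed every second wave with
occasional acute spikes, stage-specific BMD decline, HT initiation and
evolving covariates.  Ground truth (stage entry times, spike locations,
the configured CRP effects) is returned alongside for recovery testing.
"""

from crpbmd import CohortConfig, generate_cohort, summarize_cohort

config = CohortConfig(n_women=400, seed=11)
visits, truth = generate_cohort(config)

print(f"{len(visits)} visit records for {config.n_women} women "
      f"({visits['crp'].notna().sum()} CRP assays, "
      f"{len(truth.spikes)} injected acute spikes)")

summary = summarize_cohort(visits)
print("\nBaseline characteristics (mean +/- SD at first visit):")
for _, row in summary.continuous.iterrows():
    print(f"  {row['variable']:>10}: {row['mean']:7.2f} +/- {row['sd']:.2f}")

stage1 = summary.categorical.query("variable == 'stage' and level == 1")["pct"].iloc[0]
print(f"\n{stage1:.1f}% of women are premenopausal/early-perimenopausal (stage 1) at entry;")
print("the log2 CRP mean near 0.53 corresponds to a geometric-mean CRP of ~1.4 mg/L.")
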