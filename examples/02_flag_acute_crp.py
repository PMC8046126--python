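"""Flag acute-inflammation CRP values with the individual-specific rule.

A value is acute only if it is a large multiple (f = 2..6, depending on the
comparator) of the same woman's other measurements -- so a transient spike
above a low baseline is removed while chronically high but stable values
are kept, unlike an absolute 10 mg/L cut-point.
"""

from crpbmd import (
    CohortConfig, classify_acute, classify_cohort, compare_with_absolute,
    generate_cohort,
)

# A spike above a low baseline is flagged ...
series = list(enumerate([0.5, 0.6, 0.5, 0.7, 12.0]))
res = classify_acute(series)
print(f"series {[v for _, v in series]}: flagged visits {res.flagged_visit_ids} "
      f"via {res.step_triggered} (comparator {res.comparator_used}, "
      f"f = {res.multiplier_used:.0f})")

# ... but a high, stable profile is untouched.
res = classify_acute(list(enumerate([8, 9, 10, 11, 12])))
print(f"series [8, 9, 10, 11, 12]: flagged visits {res.flagged_visit_ids} "
      "(stable chronic elevation, retained)")

# Cohort-level comparison against the absolute cut-point.
visits, _ = generate_cohort(CohortConfig(n_women=500, seed=21))
flags = classify_cohort(visits)
comp = compare_with_absolute(visits, flags, cutpoint=10.0)
print(f"\n{comp['n_crp_observations']} CRP observations: hierarchical rule flags "
      f"{comp['hierarchical_total']}, the 10 mg/L cut-point would flag "
      f"{comp['absolute_total']}.")
print(f"{comp['retained_high']} chronically-high values are retained by the "
      f"hierarchy; {comp['flagged_low']} sub-cut-point spikes are caught.")
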