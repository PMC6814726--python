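"""Synthetic observer cohort -> group statistics.

Draws binomial response tables for a 9-observer cohort at the group
dominance levels of the window-boundary conditions, applies the
prerequisite exclusion rule, and summarizes with mean/SEM and a
Holm-corrected paired comparison.
"""

from sqmsim import (
    CohortSpec,
    ExclusionRule,
    dominance_summary,
    exclusion_filter,
    generate_cohort,
    holm_adjust,
    paired_test,
)

spec = CohortSpec.uniform(
    9,
    {("V-AV8", "R2"): 0.522, ("V-AV12", "R2"): 0.274},
    lapse_rate=0.02,
    trials_per_condition=160,
    seed=42,
)
summary, _ = generate_cohort(spec)
retained, log = exclusion_filter(summary, [ExclusionRule()])
print(f"observers retained: {retained['observer_id'].nunique()} "
      f"(excluded: {log['observer_id'].tolist() or 'none'})\n")
print(dominance_summary(retained).to_string(index=False))

wide = retained.pivot(index="observer_id", columns="condition", values="dominance")
cmp = paired_test(wide["V-AV8"], wide["V-AV12"], "V-AV8", "V-AV12")
p_adj = holm_adjust([cmp.p_value])[0]
print(f"\nV-AV8 vs V-AV12: t({cmp.df}) = {cmp.t_statistic:.2f}, "
      f"p_holm = {p_adj:.2g}, d = {cmp.cohens_d:.2f}, "
      f"95% CI [{cmp.ci95[0]:.2f}, {cmp.ci95[1]:.2f}]")
print("\nThe near-chance V-AV8 and flank-dominated V-AV12 group levels "
      "are cleanly separated even in a 9-observer cohort.")
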