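"""Power and sample size for the paired t-test via the noncentral t.

The paradigm's effect sizes are large (Cohen's d around 1.5-2), so
small cohorts suffice.
"""

from sqmsim import min_n_for_power, power_paired_t

power = power_paired_t(d=1.47, n=8, alpha=0.05, tails="two")
print(f"power at d=1.47, n=8 observers (two-sided, alpha=.05): {100*power:.1f}%")

n = min_n_for_power(d=2.0, target_power=0.90)
print(f"observers needed for 90% power at d=2.0: {n}")

for n_obs in (4, 5, 6, 8, 10):
    print(f"  n={n_obs:2d}: power {100*power_paired_t(2.0, n_obs):5.1f}%")
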