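"""Monte-Carlo dominance of the window-boundary conditions.

Reproduces the discrete-window signature: a frame-8 anti-vernier
(330 ms, same window as the central vernier) cancels and leaves the
report at chance, while a frame-12 anti-vernier (490 ms, next window)
is reported almost as well as an isolated vernier.
"""

from sqmsim import Instruction, simulate_condition

for name, report in [("V", None), ("V-AV8", Instruction.R2),
                     ("V-AV12", Instruction.R2)]:
    est = simulate_condition(name, n_trials=5000, seed=1, report=report)
    label = f"{name} [{est.report.value}]"
    print(f"{label:16s} dominance {est.dominance:5.1f}% "
          f"(SEM {est.sem:.1f}, window {est.window_used})")

print("\nDominance is the percentage of simulated reports in accordance "
      "with the central vernier; ~75% marks a lone visible vernier, "
      "~50% complete within-window cancellation, ~25% a dominating "
      "anti-vernier.")
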