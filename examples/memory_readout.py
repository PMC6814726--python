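"""Stage 1 on its own: leaky integration, buffering and window readout.

A lone 20-ms vernier buffers tau*(1 - exp(-0.02/tau)) of evidence; by
default that buffer is normalized to 1.  Offsets inside one 425-ms
window sum (and cancel); offsets in different windows never interact.
"""

from sqmsim import (
    ModelParams,
    build_sequence,
    get_condition,
    run_stage1,
    single_vernier_evidence,
)
from sqmsim.runner import readouts_to_table

params = ModelParams()
print(f"raw single-vernier buffer at tau={params.tau}s: "
      f"{single_vernier_evidence(params.tau):.6f} (normalized to 1.0)\n")

for name in ("V", "V-AV8", "V-AV12", "V-AV8-PV12"):
    readouts = run_stage1(build_sequence(get_condition(name)), params)
    summed = {r.window_index: round(r.summed_evidence, 3) for r in readouts}
    print(f"{name:12s} window sums: {summed}")

print("\nV-AV8-PV12: the frame-8 anti-vernier cancels the central "
      "vernier inside window 1, while the frame-12 pro-vernier is "
      "alone in window 2 — exactly the printed integration pattern.")
print(readouts_to_table(run_stage1(
    build_sequence(get_condition("V-AV8-PV12")), params)).to_string(index=False))
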