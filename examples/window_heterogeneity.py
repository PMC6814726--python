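"""Observer-specific integration windows.

A flank anti-vernier at 450 ms (frame 11) sits just outside a 425-ms
window but inside a 475-ms one: short-window observers can report the
central vernier when instructed, long-window observers cannot.
"""

from sqmsim import Instruction, ModelParams, simulate_condition

for T in (425.0, 475.0):
    est = simulate_condition(
        "V-AV11", ModelParams(T_readout_ms=T), n_trials=4000, seed=3,
        report=Instruction.R1,
    )
    print(f"T_readout = {T:.0f} ms: V-AV11 [R1] dominance {est.dominance:5.1f}% "
          f"(window read: {est.window_used})")

print("\n~75% = the central vernier is separable (the 450-ms flank fell "
      "into the next window); ~50% = mandatory integration cancelled it.")
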