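# sqmsim

Simulation and analysis toolkit for **discrete-time-window feature
integration** in the sequential metacontrast paradigm (SQM).

In the SQM a central vertical line is followed by pairs of flanking
lines drawn further and further from the center, eliciting two
apparent-motion streams. When a line carries a vernier offset (its
lower segment shifted left/right), the offset is perceived in the
attended stream — and offsets presented within several hundred
milliseconds of each other *integrate mandatorily*: observers cannot
report them individually, opposite offsets cancel, equal offsets add.
Crucially, integration happens only between offsets that fall in the
same discrete window of time anchored at stimulus onset; offsets in
different windows stay separable even when they are closer in space
and time.

`sqmsim` implements a two-stage computational account of this
behaviour and the psychophysics statistics used to analyse it:

1. **Stage 1 — memory boxes.** Each line element opens a leaky
   integrator at its retinal location, dE/dt = −E/τ + stim(t), with
   stim(t) = +1 during a pro-vernier, −1 during an anti-vernier, 0
   otherwise. When the element disappears the box closes and buffers
   E. At the end of each discrete window of duration T_readout
   (default 425 ms) the buffered evidence of the window's boxes is
   summed: ΣE.
2. **Stage 2 — attractor decision.** The window's percept is decided
   by a reduced two-variable attractor network (Wong–Wang): the input,
   drawn once per trial from N(c·ΣE, σ), antisymmetrically biases the
   external drives μ0·(1 ± input) of a "pro" and an "anti" population;
   the first population to cross a firing-rate threshold determines
   the reported offset direction.

Monte-Carlo simulation of many trials yields **dominance** — the
percentage of reports in accordance with a reference vernier — for all
conditions of the four SQM experiments. The fitted parameters are
τ = 0.3 s, c = 0.3, σ = 0.2, μ0 = 0.2, T_readout = 425 ms.

The package also provides the accompanying statistics (group mean
dominance and SEM, two-sided paired t-tests with Holm correction,
Cohen's d with noncentral-t confidence intervals, power and sample
size for the paired design) and a generator of synthetic observer
cohorts — binomial response tables with per-observer lapse rates and
heterogeneous integration-window durations — so the whole pipeline is
testable without human data.

## Worked example

```python
from sqmsim import Instruction, simulate_condition

for name, report in [("V", None), ("V-AV8", Instruction.R2),
                     ("V-AV12", Instruction.R2)]:
    est = simulate_condition(name, n_trials=5000, seed=1, report=report)
    print(f"{name} [{est.report.value}]  dominance {est.dominance:.1f}% "
          f"(SEM {est.sem:.1f})")
```

prints

```
V [naive]  dominance 72.8% (SEM 0.6)
V-AV8 [R2]  dominance 49.3% (SEM 0.7)
V-AV12 [R2]  dominance 26.6% (SEM 0.6)
```

A lone central vernier (condition V) is reported correctly on ~73% of
trials. Adding an anti-vernier in frame 8 (330 ms — inside the same
425-ms window) cancels it exactly, leaving the report at chance even
when observers are instructed to report the flank ("V-AV8 [R2]"). An
anti-vernier in frame 12 (490 ms — in the *next* window) does not
integrate and is reported almost as well as an isolated vernier
(dominance relative to the central direction falls to ~27%). These
match the group values observed with human observers (~75%, 52.2%,
27.4%).

The `examples/` directory has one short script per capability:
stimulus timing, stage-1 readout, condition simulation, power
analysis, cohort statistics, and per-observer window heterogeneity.

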