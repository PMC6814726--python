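# Methods

## The model

The package implements a two-stage account of long-lasting feature
integration in the sequential metacontrast paradigm (SQM).

**Stimulus.** An SQM sequence is a central line (frame 0, onset 0 ms)
followed by `n_pairs` pairs of flanking lines. Every line lasts 20 ms;
the first inter-stimulus interval is 30 ms and all later ones 20 ms,
so flanking frame n starts at 50 + 40·(n−1) ms. Total duration is the
last frame's onset plus 20 ms: 750 ms for the classic 18-pair
sequence, 830 ms for the extended 20-pair one. Neighbouring
eccentricities are 10/3 arcmin apart (the per-gap value implied by the
printed multi-gap separations of 13.3′ over four gaps and 26.7′ over
eight; the rounded single-gap figure is 3.3′). Offsets are encoded
only by direction: stim(t) = +1 while a pro-vernier is shown, −1 for
an anti-vernier, 0 otherwise. Offset *magnitude* (arcmin) is carried
as metadata and never enters the model — conditions whose behavioural
strength was equated by per-observer offset-size calibration are
therefore represented as equal-magnitude ±1 signals. Offsets are
applied only to the attended stream; the unattended stream never
integrates with it and is not modelled. Stimulus-level times are exact
integer milliseconds; conversion to seconds happens inside the
integrator.

In the diverging-then-converging variant the eccentricity trajectory
reverses at frame 10; timing and location bookkeeping are unchanged,
and since stage 1 sums over the attended stream regardless of
position, the variant only affects the geometry columns of the
exported sequence table. Flank lengths for that variant use the
constant-20′ geometry (its lengths are not separately specified, and
they are irrelevant to model output).

**Stage 1.** Each attended-stream element opens a memory box at its
location which leaky-integrates its signal, dE/dt = −E/τ + stim(t),
noise-free, from E = 0 at element onset. The closed form for a
constant segment is used (E ← E·e^(−Δ/τ) + s·τ·(1 − e^(−Δ/τ))); tests
verify agreement with a forward-Euler oracle to 1e−6. At element
offset the box closes and buffers E unchanged (no decay after
buffering). Time is partitioned into consecutive readout windows of
T_readout ms anchored at stimulus onset; a box belongs to the window
containing its element's **onset** (in every stock condition the
offset elements lie strictly inside one window — frame 10, the only
straddling candidate at 410–430 ms, is never offset — so the boundary
rule is unobservable; onset assignment is the simplest consistent
choice). At the end of window k the buffered evidence of its boxes is
summed, with no crosstalk between windows. The number of simulated
windows is ceil(duration / T_readout), which is 2 for every stock
condition.

**Evidence normalization.** The raw buffer of one 20-ms unit vernier
at τ = 0.3 s is τ·(1 − e^(−0.02/τ)) ≈ 0.0193. The published parameter
set (c = 0.3, σ = 0.2, μ0 = 0.2) only produces graded dominance if ΣE
is of order 1 — with raw seconds-scale evidence the input distribution
N(c·ΣE, σ) would be indistinguishable from noise and every condition
would sit at chance, contradicting the fitted ~75% dominance of
condition V. Buffered evidence is therefore divided at readout by the
single-vernier buffer magnitude, so one isolated vernier contributes
exactly ±1 to ΣE. This is a pure rescaling: it preserves all
cancellation, sign and additivity structure. The raw scale remains
available via `evidence_scale=1.0`.

**Stage 2.** The decision input is drawn once per trial from
N(c·ΣE, σ). The decision is made by the reduced two-variable
mean-field formulation of the Wong–Wang attractor network, with its
published physiological constants: transfer function
H(x) = (a·x − b)/(1 − e^(−d·(a·x − b))) with a = 270 Hz/nA,
b = 108 Hz, d = 0.154 s; gating dynamics
dS_i/dt = −S_i/τ_S + (1 − S_i)·γ·H(x_i) with τ_S = 0.1 s, γ = 0.641;
currents x_i = J_ii·S_i − J_ij·S_j + I0 + I_ext,i + I_noise,i with
J11 = J22 = 0.2609 nA, J12 = J21 = 0.0497 nA, I0 = 0.3255 nA;
Ornstein–Uhlenbeck background noise with τ_noise = 2 ms and stationary
SD 0.02 nA (exact-update discretization, initialized at
stationarity); threshold 15 Hz; Euler step 0.5 ms; T_max = 2 s.

The scalar input enters through the background drive: population
"pro" receives I_ext = J_ext·μ0·(1 + input), population "anti"
J_ext·μ0·(1 − input). Antisymmetric biasing is the minimal mapping
with the required zero-input symmetry. The drive scale J_ext is the
model's one hand-fitted constant: it sets how sharply the network
discriminates a given input against its own background noise, and was
fixed once at **J_ext = 0.0095 nA** so that the full pipeline
reproduces the ~75% dominance of a lone vernier (and, by the model's
antisymmetry, the ~25–27% of a lone anti-vernier) at the published
(τ, c, σ, μ0). It is deliberately weak: perceptual decisions about
near-threshold verniers are noise-limited, and a strong drive would
push every condition to ceiling. If neither population crosses
threshold by T_max the higher final rate wins, with exact ties broken
by a fair coin; at the default parameters roughly half the trials
resolve by threshold crossing and the rest by this (still
evidence-correlated) fallback.

**Report mapping.** [R1] ("report the first vernier") reads window 1,
[R2] window 2; requesting [R2] of a stimulus spanning a single window
is an error. Naive observers give one response; the model reads the
most recent window with non-zero summed evidence, falling back to the
last window when everything cancelled. This naive rule is a
construction of this package (the readout driving the single naive
response is not specified by the source description): it is the
simplest rule consistent with the observed naive pattern — a lone
vernier ≈ 75%, a same-window anti-vernier ≈ 50%, a late (570 ms)
anti-vernier ≈ 25%. It does *not* reproduce the naive group level at
frame 11 (450 ms), where human observers still integrate (~50%) but a
425-ms model window has the flank in window 2 (~25–27%); the observed
per-observer heterogeneity of window duration (see below) is the
model's account of that condition, and no crosstalk parameter is
added for the small [R1] spill-over in V-AV8-PV12.

**Dominance.** A condition's dominance is the percentage of simulated
choices in accordance with its reference vernier: the central offset
where one exists (falling back to the nominal pro direction for
flank-only conditions), or the earliest/latest offset for
first-/second-vernier references. Flipping the reference complements
dominance exactly; flipping every stimulus offset complements the
probability of a pro choice.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| τ | 0.3 | s | memory-box leak time constant |
| c | 0.3 | — | readout gain on ΣE |
| σ | 0.2 | — | SD of the decision-input draw |
| μ0 | 0.2 | — | background drive of the decision network |
| T_readout | 425 | ms | window duration (475 ms for long-window observers) |
| evidence_scale | single-vernier buffer | — | ΣE normalization divisor |
| J_ext | 0.0095 | nA | external-drive scale (hand-fitted, see above) |

All stage-2 constants are exposed on `DecisionNetworkParams`;
parameter files (`save_params`/`load_params`) use the keys τ, c, σ,
μ0, T_readout_ms, evidence_scale plus a `network` section.

## Experiment library

The condition library encodes every named condition: V, AV, V-PVn and
V-AVn for n ∈ {1, 2, 3, 5, 7, 11, 14}, the window-boundary set V-AV8,
V-AV12, V-AV8-PV12, the no-central-offset set PV8-PV12, PV8-AV12,
PV1-AV5, and the extended conditions C1–C5. For C1–C5 the offset
*frames* follow the calibration groups (1, 5, 8 before the window
boundary; 12, 15, 19 after), with pro/anti signs arranged so each
group's two same-direction offsets oppose its single opposite one.
Because the model encodes every offset as ±1 while the behavioural
experiment equated two-against-one groups by offset-size calibration,
the C-condition group sums are ±1 rather than 0; their simulated
dominances are therefore not comparable to the behavioural ~50% levels
and the library documents structure, not fitted magnitudes. The lone
AV condition places its anti-vernier in frame 5 (a representative
mid-stream position; the original position is not specified).

`reproduce_experiment(1)` additionally runs the informed [R1]
conditions at T_readout = 475 ms: about half the observers could not
report the central vernier at the 450-ms flank even when instructed,
and assigning those observers a longer window reproduces their
mandatory integration while the 425-ms window reproduces the others.

## Synthetic cohorts

`generate_cohort` draws per-observer binary response tables: each
(observer, condition) cell is binomial with success probability
p·(1 − lapse) + lapse/2, at 160 trials per condition (80-trial
blocks, each condition measured twice). Probabilities come either
from an explicit map or, in "model" mode, from running the simulator
under each observer's own T_window — which reproduces the observed
split between ~425-ms and ~475-ms integrators. The default lapse rate
of 0.02 keeps synthetic psychometrics realistically imperfect; exact
parameter-recovery tests use 0.

The generator emulates the *statistical* structure of group data —
binomial trial noise, observer heterogeneity in window duration,
lapses — and nothing else: no learning or fatigue across blocks, no
criterion drift, no offset-size psychometrics (PEST calibration is
outside the model), no reaction times. Tests passing on synthetic
cohorts therefore validate the pipeline's statistics and the model's
structural predictions, not the behavioural group curves themselves,
which beyond the anchor values (V ≈ 75%, V-AV8 [R2] = 52.2%,
V-AV12 [R2] = 27.4%) are not reproducible from the published numbers.

**Exclusion rule.** Observers whose prerequisite conditions
contradict each other — V-AV8 dominance indicating no integration
while V-AV12 fails to indicate flank dominance — are excluded. The
narrative description gives no numeric cut-offs; the package
operationalizes "indicates no integration" as dominance ≤ 35% and the
excluded pattern as (V-AV8 ≤ 35) ∧ (V-AV12 > 35), which reproduces
the reported exclusion case (28.4%, 45%) without inventing precision.
Thresholds and condition names are configurable (`ExclusionRule`), so
the analogous chance-level V-PV rule can be expressed the same way.

## Statistics

Group summaries use the mean of observer dominances and
SEM = sd/√n. Paired comparisons use the classical paired t on
differences; Cohen's d for the paired design is mean(diff)/sd(diff)
(equivalently t/√n), with a 95% CI by noncentral-t pivot inversion.
Identical samples give t = 0, d = 0, p = 1; a constant non-zero shift
(sd(diff) = 0) is flagged degenerate instead of producing a p-value.
Holm's step-down correction is applied via statsmodels. Power for the
paired/one-sample t-test is P(|T′| > t_crit) with T′ noncentral t,
df = n − 1, noncentrality d·√n, two-sided α = 0.05 by default; the
printed 94.3% at d = 1.47, n = 8 is reproduced by the two-sided
computation, so no one-sided variant is silently substituted (the
one-sided option is available explicitly). scipy's noncentral-t CDF
can return NaN deep in a tail; a guarded wrapper falls back to the
complement and, for genuine underflow, to the tail limit.

## Numerical and design choices

- Monte-Carlo trials are vectorized: the whole batch of network
  simulations advances together with an active-set mask, with one
  seeded generator per (seed, window) pair; identical (seed, params,
  condition) calls are bit-reproducible. A per-trial generator would
  make single trials reproducible independently of batch size but
  costs an order of magnitude in runtime for no statistical benefit.
- Default 10,000 trials per condition gives a binomial SE ≤ 0.5
  percentage points at p = 0.5; unit tests use 1,000–3,000 trials
  (SE ≲ 1 pp) with 3·SE assertion bands.
- The OU background noise uses the exact one-step update
  I ← I·e^(−Δ/τ_n) + σ_n·√(1 − e^(−2Δ/τ_n))·ξ, so its stationary SD
  is σ_n independent of the step size.
- The transfer function's removable singularity at a·x = b is handled
  explicitly (limit 1/d) and its exponent clipped against overflow.
- Empty windows read out exactly 0 and drive a chance-level decision;
  degenerate all-cancelled naive trials read the last window.

## Limitations

- The naive-report rule and the C1–C5 sign encoding are
  reconstructions (flagged above); dominance magnitudes for C1–C5 are
  structural, not fitted.
- The model has no window-boundary straddling rule (never exercised
  by the stock conditions) and no cross-window leakage.
- Stage 2's constants beyond μ0 follow the published reduced-model
  values; the original implementation may differ in unpublished
  details, so model dominances carry a few percentage points of
  implementation uncertainty in addition to Monte-Carlo error.
- Reaction times are bookkeeping only (threshold-crossing times of
  the attractor network); they are not fitted to behaviour.
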