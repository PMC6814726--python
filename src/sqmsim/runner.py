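"""Monte-Carlo simulation of whole SQM conditions and experiments.

A condition is simulated by one deterministic stage-1 pass (memory
boxes and window readouts) followed by independent stage-2 decision
trials on the window selected by the report instruction:

* R1 -> window 1, R2 -> window 2 (the first/second percept);
* naive observers give a single response, modelled as a readout of the
  most recent window holding non-zero evidence (the latest percept
  with a visible offset), falling back to the last window when every
  window cancelled.

Dominance is the percentage of choices in accordance with the
condition's reference vernier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import get_condition
from .decision import DecisionNetworkParams, decide_batch
from .memory import ModelParams, WindowReadout, run_stage1
from .stimulus import (
    ConditionSpec,
    Geometry,
    Instruction,
    Reference,
    Variant,
    build_sequence,
)

__all__ = [
    "DominanceEstimate",
    "report_window",
    "simulate_condition",
    "reproduce_experiment",
    "readouts_to_table",
]

#: Window duration (ms) of the long-integration observer subgroup.
LONG_WINDOW_MS = 475.0


@dataclass(frozen=True)
class DominanceEstimate:
    """Monte-Carlo dominance of one condition.

    ``dominance`` is the percentage of simulated choices in accordance
    with the reference vernier; ``sem`` is the binomial standard error
    of that percentage across trials.
    """

    condition_name: str
    report: Instruction
    n_trials: int
    dominance: float
    sem: float
    window_used: int

    def flipped(self) -> "DominanceEstimate":
        return DominanceEstimate(
            condition_name=self.condition_name,
            report=self.report,
            n_trials=self.n_trials,
            dominance=100.0 - self.dominance,
            sem=self.sem,
            window_used=self.window_used,
        )


def report_window(
    readouts: list[WindowReadout], instruction: Instruction
) -> int:
    """Map a report instruction to the window index it reads.

    R1 and R2 address the first and second window.  Naive observers
    report the most recent window with non-zero summed evidence (the
    last visible offset percept), or the last window if all cancelled.
    """
    if not readouts:
        raise ValueError("need at least one window readout")
    if instruction is Instruction.R1:
        return 1
    if instruction is Instruction.R2:
        if len(readouts) < 2:
            raise ValueError(
                "R2 requested but the stimulus spans a single readout window"
            )
        return 2
    nonzero = [r.window_index for r in readouts if r.summed_evidence != 0.0]
    return nonzero[-1] if nonzero else readouts[-1].window_index


def _default_geometry(spec: ConditionSpec) -> Geometry:
    # the extended converging sequences use constant 20' lines
    if spec.variant is Variant.DIVERGING_THEN_CONVERGING:
        return Geometry.constant()
    return Geometry.growing()


def simulate_condition(
    spec: ConditionSpec | str,
    params: ModelParams | None = None,
    net: DecisionNetworkParams | None = None,
    n_trials: int = 10_000,
    seed: int = 0,
    report: Instruction | None = None,
    reference: Reference | None = None,
    geometry: Geometry | None = None,
    return_trials: bool = False,
) -> DominanceEstimate | tuple[DominanceEstimate, pd.DataFrame]:
    """Monte-Carlo dominance estimate for one condition.

    Stage 1 runs once (it is deterministic); each of the ``n_trials``
    stage-2 trials draws its own noisy decision input and network-noise
    realization.  The random stream is derived from ``(seed, window)``
    so identical calls are bit-reproducible.
    """
    if isinstance(spec, str):
        spec = get_condition(spec)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or ModelParams()
    net = net or DecisionNetworkParams()
    report = report or spec.instruction
    geometry = geometry or _default_geometry(spec)

    seq = build_sequence(spec, geometry)
    readouts = run_stage1(seq, params)
    window = report_window(readouts, report)
    evidence = readouts[window - 1].summed_evidence

    rng = np.random.default_rng([seed, window])
    inputs = rng.normal(params.c * evidence, params.sigma, size=n_trials)
    choices, decided, times = decide_batch(inputs, params.mu0, net, rng)

    ref_sign = spec.reference_sign(reference)
    in_accordance = choices == ref_sign
    p = in_accordance.mean()
    est = DominanceEstimate(
        condition_name=spec.name,
        report=report,
        n_trials=n_trials,
        dominance=100.0 * p,
        sem=100.0 * float(np.sqrt(p * (1.0 - p) / n_trials)),
        window_used=window,
    )
    if not return_trials:
        return est
    trials = pd.DataFrame(
        {
            "condition": spec.name,
            "report": report.value,
            "trial": np.arange(n_trials),
            "window_used": window,
            "input": inputs,
            "choice": choices,
            "in_accordance": in_accordance,
            "decided": decided,
            "decision_time_s": times,
        }
    )
    return est, trials


def _estimate_row(est: DominanceEstimate, T_readout_ms: float) -> dict:
    return {
        "condition": est.condition_name,
        "report": est.report.value,
        "T_readout_ms": T_readout_ms,
        "n_trials": est.n_trials,
        "dominance": est.dominance,
        "sem": est.sem,
        "window_used": est.window_used,
    }


def reproduce_experiment(
    experiment_id: int,
    params: ModelParams | None = None,
    net: DecisionNetworkParams | None = None,
    n_trials: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Model dominance table for one of the four experiments.

    Experiment 1 additionally simulates the informed [R1] conditions
    with the long 475-ms window of the slow-integration observer
    subgroup, alongside the default window.
    """
    params = params or ModelParams()
    net = net or DecisionNetworkParams()
    rows: list[dict] = []

    def run(name, report, p=None, reference=None, geometry=None):
        p = p or params
        est = simulate_condition(
            name, p, net, n_trials=n_trials, seed=seed, report=report,
            reference=reference, geometry=geometry,
        )
        rows.append(_estimate_row(est, p.T_readout_ms))

    if experiment_id == 1:
        for name in ("V", "AV"):
            run(name, Instruction.NAIVE)
        for n in (7, 11, 14):
            run(f"V-AV{n}", Instruction.NAIVE)
            run(f"V-PV{n}", Instruction.NAIVE)
        long_params = params.with_window(LONG_WINDOW_MS)
        for n in (7, 11, 14):
            run(f"V-AV{n}", Instruction.R1)
            run(f"V-AV{n}", Instruction.R1, p=long_params)
    elif experiment_id == 2:
        run("V-AV8", Instruction.R2)
        run("V-AV12", Instruction.R2)
        run("V-AV8-PV12", Instruction.R1)
        run("V-AV8-PV12", Instruction.R2)
    elif experiment_id == 3:
        # constant 20' flank lengths in this experiment
        for name in ("PV8-PV12", "PV8-AV12"):
            run(name, Instruction.R1, reference=Reference.FIRST,
                geometry=Geometry.constant())
            run(name, Instruction.R2, reference=Reference.SECOND,
                geometry=Geometry.constant())
    elif experiment_id == 4:
        for k in range(1, 6):
            run(f"C{k}", Instruction.R1, reference=Reference.FIRST)
            run(f"C{k}", Instruction.R2, reference=Reference.SECOND)
    else:
        raise ValueError(f"experiment_id must be 1..4, got {experiment_id}")

    return pd.DataFrame(rows)


def readouts_to_table(readouts: list[WindowReadout]) -> pd.DataFrame:
    """Window-readout trace export, one row per window."""
    return pd.DataFrame(
        {
            "window_index": [r.window_index for r in readouts],
            "t_readout_ms": [r.t_readout_ms for r in readouts],
            "summed_evidence": [r.summed_evidence for r in readouts],
        }
    )
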