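"""Stage 1: per-location memory boxes with leaky integration.

Each line element of the attended stream opens a memory box at its
retinal location.  While the element is on screen the box integrates
the feature signal stim(t) in a noise-free leaky integrator

    dE/dt = -E/tau + stim(t),

and when the element disappears the box closes, buffering its current
evidence E unchanged.  Time is partitioned into consecutive readout
windows of duration T_readout starting at stimulus onset; at the end
of each window the buffered evidence of all boxes whose element
started inside that window is summed.  Evidence never crosses window
boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .stimulus import PiecewiseConstant, StimulusSequence, element_signal

__all__ = [
    "ModelParams",
    "MemoryBox",
    "WindowReadout",
    "integrate_box",
    "assign_window",
    "build_memory_boxes",
    "window_readout",
    "run_stage1",
    "single_vernier_evidence",
]


def single_vernier_evidence(tau: float, duration_ms: float = 20.0) -> float:
    """Buffered evidence of one isolated unit-signal line.

    Closed form for constant input s=1 over ``duration_ms``:
    tau * (1 - exp(-d/tau)) with d in seconds.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    return tau * (1.0 - math.exp(-(duration_ms / 1000.0) / tau))


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-stage model.

    tau : float
        Leaky-integration time constant of the memory boxes, seconds.
    c : float
        Gain applied to the summed window evidence before the decision
        network.
    sigma : float
        Standard deviation of the Gaussian readout noise on the
        decision-network input.
    mu0 : float
        Background input of the decision network (its only free
        parameter): the drive both populations receive in the absence
        of evidence.
    T_readout_ms : float
        Duration of one integration window, milliseconds.  425 ms for
        all simulations except the long-window observers, which use
        475 ms.
    evidence_scale : float or None
        Normalization divisor applied to buffered evidence at readout.
        ``None`` (the default) normalizes by the single-vernier buffer
        magnitude tau*(1 - exp(-0.02/tau)), so that one isolated 20-ms
        vernier contributes exactly +/-1 to the window sum; set 1.0 to
        keep evidence on the raw seconds scale.
    """

    tau: float = 0.3
    c: float = 0.3
    sigma: float = 0.2
    mu0: float = 0.2
    T_readout_ms: float = 425.0
    evidence_scale: float | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.T_readout_ms <= 0:
            raise ValueError(f"T_readout_ms must be > 0, got {self.T_readout_ms}")
        if self.evidence_scale is not None and self.evidence_scale <= 0:
            raise ValueError("evidence_scale must be > 0 or None")

    def resolved_evidence_scale(self) -> float:
        if self.evidence_scale is not None:
            return self.evidence_scale
        return single_vernier_evidence(self.tau)

    def with_window(self, T_readout_ms: float) -> "ModelParams":
        return replace(self, T_readout_ms=T_readout_ms)


@dataclass(frozen=True)
class MemoryBox:
    """A closed memory box: buffered evidence of one line element."""

    location_id: int
    t_open: float
    t_close: float
    E_buffered: float
    window_index: int


@dataclass(frozen=True)
class WindowReadout:
    """Summed (normalized) evidence of one integration window."""

    window_index: int
    t_readout_ms: float
    summed_evidence: float


def integrate_box(signal: PiecewiseConstant, tau: float) -> float:
    """Leaky-integrate a piecewise-constant signal; return E at its end.

    Exact solution segment by segment: over a constant segment of value
    s and length dt, E(t+dt) = E(t)*exp(-dt/tau) + s*tau*(1-exp(-dt/tau)).
    Integration starts from E=0 at the signal's first breakpoint.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    E = 0.0
    for start_ms, end_ms, value in signal.segments():
        dt = (end_ms - start_ms) / 1000.0
        decay = math.exp(-dt / tau)
        E = E * decay + value * tau * (1.0 - decay)
    return E


def assign_window(t_open_ms: float, T_readout_ms: float) -> int:
    """Window containing an element that starts at ``t_open_ms``.

    Windows are 1-based, consecutive, and anchored at stimulus onset:
    window k covers [(k-1)*T, k*T).  Assignment is by element onset.
    """
    if t_open_ms < 0:
        raise ValueError(f"t_open_ms must be >= 0, got {t_open_ms}")
    if T_readout_ms <= 0:
        raise ValueError(f"T_readout_ms must be > 0, got {T_readout_ms}")
    return int(math.floor(t_open_ms / T_readout_ms)) + 1


def build_memory_boxes(seq: StimulusSequence, params: ModelParams) -> list[MemoryBox]:
    """One closed box per attended-stream element (center included).

    Unattended-stream elements are never offset and never integrate
    with the attended stream, so they are not modelled.
    """
    boxes = []
    for loc in seq.attended_location_ids:
        sig = element_signal(seq, loc)
        e = seq.element_at(loc)
        boxes.append(
            MemoryBox(
                location_id=loc,
                t_open=float(e.onset),
                t_close=float(e.offset_end),
                E_buffered=integrate_box(sig, params.tau),
                window_index=assign_window(e.onset, params.T_readout_ms),
            )
        )
    return boxes


def window_readout(
    boxes: list[MemoryBox], window_index: int, params: ModelParams
) -> WindowReadout:
    """Sum the normalized buffered evidence of one window's boxes.

    An empty window reads out 0, which drives a chance-level decision.
    """
    scale = params.resolved_evidence_scale()
    total = sum(b.E_buffered for b in boxes if b.window_index == window_index)
    return WindowReadout(
        window_index=window_index,
        t_readout_ms=window_index * params.T_readout_ms,
        summed_evidence=total / scale,
    )


def n_windows(seq: StimulusSequence, params: ModelParams) -> int:
    """Number of readout windows spanning the whole stimulus."""
    return max(1, math.ceil(seq.duration_ms / params.T_readout_ms))


def run_stage1(seq: StimulusSequence, params: ModelParams) -> list[WindowReadout]:
    """Deterministic stage-1 pass: boxes, then one readout per window."""
    boxes = build_memory_boxes(seq, params)
    return [
        window_readout(boxes, k, params) for k in range(1, n_windows(seq, params) + 1)
    ]
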