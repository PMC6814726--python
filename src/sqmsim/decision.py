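"""Stage 2: binary perceptual decision via a reduced attractor network.

The window's summed evidence is first converted to a scalar network
input by a single Gaussian draw, input ~ N(c * sum(E), sigma).  The
decision itself is made by the reduced two-variable mean-field
attractor network of Wong & Wang (2006): two populations ("pro" and
"anti"), each summarized by its slow NMDA gating variable S, with
recurrent self-excitation and cross-inhibition, a nonlinear
firing-rate transfer function, and Ornstein-Uhlenbeck background
current noise.  The scalar input biases the two populations' external
drives antisymmetrically around the background input mu0:

    I_ext,pro  = J_ext * mu0 * (1 + input)
    I_ext,anti = J_ext * mu0 * (1 - input)

so zero input leaves the network perfectly symmetric.  The first
population whose firing rate crosses the decision threshold wins; if
neither crosses within T_max, the population with the higher final
rate wins (exact ties are broken by a fair coin).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DecisionNetworkParams",
    "Choice",
    "DecisionOutcome",
    "draw_decision_input",
    "run_decision_network",
    "decide_batch",
]


@dataclass(frozen=True)
class DecisionNetworkParams:
    """Constants of the reduced two-variable attractor network.

    Except for the external drive scale ``J_ext`` (calibrated once so
    that the full two-stage model reproduces the ~75% dominance of a
    lone central vernier; see docs/methods.md) these are the published
    physiological values of the reduced model.

    a, b, d : transfer-function constants (Hz/nA, Hz, s).
    gamma : gating-variable rise constant (dimensionless).
    tau_S : NMDA gating time constant, s.
    J11, J22 : recurrent self-coupling, nA.
    J12, J21 : cross-inhibition, nA.
    J_ext : scale of the external drive J_ext * mu0 * (1 +/- input), nA.
    I0 : common background current, nA.
    tau_noise, sigma_noise : OU background-noise time constant (s) and
        stationary standard deviation (nA).
    threshold : decision firing-rate threshold, Hz.
    dt : Euler integration step, s.
    T_max : maximum decision time, s.
    S_init : initial gating value of both populations.
    """

    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    gamma: float = 0.641
    tau_S: float = 0.1
    J11: float = 0.2609
    J22: float = 0.2609
    J12: float = 0.0497
    J21: float = 0.0497
    J_ext: float = 0.0095
    I0: float = 0.3255
    tau_noise: float = 0.002
    sigma_noise: float = 0.02
    threshold: float = 15.0
    dt: float = 5e-4
    T_max: float = 2.0
    S_init: float = 0.1

    def __post_init__(self) -> None:
        for name in ("tau_S", "tau_noise", "dt", "T_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


class Choice(str, enum.Enum):
    PRO = "pro"
    ANTI = "anti"


@dataclass(frozen=True)
class DecisionOutcome:
    """Outcome of one decision trial."""

    choice: Choice
    decided: bool
    decision_time: float | None


def draw_decision_input(
    summed_evidence: float, c: float, sigma: float, rng: np.random.Generator
) -> float:
    """One draw of the decision-network input, N(c * sum(E), sigma)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    return float(rng.normal(c * summed_evidence, sigma))


def _transfer(x: np.ndarray, p: DecisionNetworkParams) -> np.ndarray:
    """Firing-rate transfer H(x) = (a*x-b) / (1 - exp(-d*(a*x-b)))."""
    z = p.a * x - p.b
    denom = 1.0 - np.exp(np.clip(-p.d * z, None, 700.0))
    out = np.where(np.abs(denom) > 1e-12, z / np.where(denom == 0, 1.0, denom), 1.0 / p.d)
    return out


def decide_batch(
    inputs: np.ndarray,
    mu0: float,
    params: DecisionNetworkParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one decision per entry of ``inputs``, vectorized.

    Returns ``(choices, decided, times)``: choices are +1 (pro) / -1
    (anti); ``times`` holds the threshold-crossing time in seconds
    (NaN where the fallback rule decided).
    """
    inputs = np.asarray(inputs, dtype=float)
    if not np.all(np.isfinite(inputs)):
        raise ValueError("decision-network input must be finite")
    n = inputs.size
    p = params
    n_steps = int(round(p.T_max / p.dt))

    # State: columns 0 = pro, 1 = anti.
    S = np.full((n, 2), p.S_init)
    I_ext = p.J_ext * mu0 * np.stack([1.0 + inputs, 1.0 - inputs], axis=1)
    # OU noise, exact update; start from the stationary distribution.
    ou_decay = math.exp(-p.dt / p.tau_noise)
    ou_kick = p.sigma_noise * math.sqrt(1.0 - ou_decay**2)
    I_noise = rng.normal(0.0, p.sigma_noise, size=(n, 2)) if p.sigma_noise > 0 else np.zeros((n, 2))

    choices = np.zeros(n, dtype=np.int8)
    times = np.full(n, np.nan)
    active = np.arange(n)
    r = np.zeros((n, 2))

    for step in range(n_steps):
        Sa = S[active]
        x = np.empty_like(Sa)
        x[:, 0] = p.J11 * Sa[:, 0] - p.J12 * Sa[:, 1] + p.I0 + I_ext[active, 0] + I_noise[active, 0]
        x[:, 1] = p.J22 * Sa[:, 1] - p.J21 * Sa[:, 0] + p.I0 + I_ext[active, 1] + I_noise[active, 1]
        ra = _transfer(x, p)
        r[active] = ra

        crossed = ra >= p.threshold
        any_crossed = crossed.any(axis=1)
        if any_crossed.any():
            done = active[any_crossed]
            rc = ra[any_crossed]
            # if both cross in the same step, the higher rate wins
            winner_pro = rc[:, 0] >= rc[:, 1]
            choices[done] = np.where(winner_pro, 1, -1)
            times[done] = step * p.dt
            keep = ~any_crossed
            active = active[keep]
            Sa = Sa[keep]
            ra = ra[keep]
            if active.size == 0:
                break

        S[active] = Sa + p.dt * (-Sa / p.tau_S + (1.0 - Sa) * p.gamma * ra)
        if p.sigma_noise > 0:
            I_noise[active] = ou_decay * I_noise[active] + ou_kick * rng.normal(
                size=(active.size, 2)
            )

    if active.size:
        # fallback: higher final rate; exact ties -> fair coin
        rf = r[active]
        diff = rf[:, 0] - rf[:, 1]
        coin = rng.integers(0, 2, size=active.size) * 2 - 1
        choices[active] = np.where(diff > 0, 1, np.where(diff < 0, -1, coin)).astype(np.int8)

    decided = ~np.isnan(times)
    return choices, decided, times


def run_decision_network(
    input: float,
    mu0: float,
    params: DecisionNetworkParams,
    rng: np.random.Generator,
    record_trajectory: bool = False,
) -> DecisionOutcome | tuple[DecisionOutcome, pd.DataFrame]:
    """Simulate a single decision trial.

    With ``record_trajectory=True`` additionally returns a DataFrame of
    (time_s, S_pro, S_anti, rate_pro, rate_anti) sampled every step,
    for diagnostics.
    """
    if not np.isfinite(input):
        raise ValueError("decision-network input must be finite")
    if not record_trajectory:
        choices, decided, times = decide_batch(np.array([input]), mu0, params, rng)
        t = float(times[0])
        return DecisionOutcome(
            choice=Choice.PRO if choices[0] > 0 else Choice.ANTI,
            decided=bool(decided[0]),
            decision_time=None if math.isnan(t) else t,
        )

    p = params
    n_steps = int(round(p.T_max / p.dt))
    S = np.full(2, p.S_init)
    I_ext = p.J_ext * mu0 * np.array([1.0 + input, 1.0 - input])
    ou_decay = math.exp(-p.dt / p.tau_noise)
    ou_kick = p.sigma_noise * math.sqrt(1.0 - ou_decay**2)
    I_noise = rng.normal(0.0, p.sigma_noise, size=2) if p.sigma_noise > 0 else np.zeros(2)
    rows = []
    outcome = None
    for step in range(n_steps):
        x = np.array(
            [
                p.J11 * S[0] - p.J12 * S[1] + p.I0 + I_ext[0] + I_noise[0],
                p.J22 * S[1] - p.J21 * S[0] + p.I0 + I_ext[1] + I_noise[1],
            ]
        )
        r = _transfer(x, p)
        rows.append((step * p.dt, S[0], S[1], r[0], r[1]))
        if outcome is None and (r >= p.threshold).any():
            outcome = DecisionOutcome(
                choice=Choice.PRO if r[0] >= r[1] else Choice.ANTI,
                decided=True,
                decision_time=step * p.dt,
            )
            break
        S = S + p.dt * (-S / p.tau_S + (1.0 - S) * p.gamma * r)
        if p.sigma_noise > 0:
            I_noise = ou_decay * I_noise + ou_kick * rng.normal(size=2)
    if outcome is None:
        r = rows[-1][3:5]
        if r[0] == r[1]:
            pro = bool(rng.integers(0, 2))
        else:
            pro = r[0] > r[1]
        outcome = DecisionOutcome(
            choice=Choice.PRO if pro else Choice.ANTI, decided=False, decision_time=None
        )
    traj = pd.DataFrame(rows, columns=["time_s", "S_pro", "S_anti", "rate_pro", "rate_anti"])
    return outcome, traj
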