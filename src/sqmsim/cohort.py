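"""Synthetic observer cohorts.

Generates per-observer binary response tables with the statistical
structure of SQM group data: binomial responses at given per-condition
dominance probabilities, a small lapse rate, and per-observer
heterogeneity of the integration-window duration (some observers
integrate for ~425 ms, others ~475 ms).  In "model" mode the response
probability of each (observer, condition, report) cell is produced by
the two-stage simulator under that observer's window duration, so the
whole pipeline — generator, model and statistics — can be exercised
without any human data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .decision import DecisionNetworkParams
from .memory import ModelParams
from .runner import simulate_condition
from .stimulus import Instruction

__all__ = [
    "ObserverProfile",
    "CohortSpec",
    "ExclusionRule",
    "generate_cohort",
    "exclusion_filter",
]

#: Trials per condition under the block design: 80-trial blocks, each
#: condition measured twice.
TRIALS_PER_CONDITION = 160


@dataclass(frozen=True)
class ObserverProfile:
    """One synthetic observer.

    ``T_window_ms`` is the individual integration-window duration;
    ``lapse_rate`` the probability of a random (coin-flip) response.
    """

    observer_id: str
    T_window_ms: float = 425.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.T_window_ms <= 0:
            raise ValueError("T_window_ms must be > 0")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5]")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``condition_probs`` maps (condition_name, report) to the response
    probability (dominance/100) shared by all observers, or is the
    string ``"model"``, in which case each observer's probability is
    estimated by running the two-stage simulator with that observer's
    window duration.
    """

    observers: tuple[ObserverProfile, ...]
    condition_probs: Mapping[tuple[str, str], float] | str
    trials_per_condition: int = TRIALS_PER_CONDITION
    seed: int = 0
    model_trials: int = 2000
    #: in "model" mode, restrict generation to these (condition, report)
    #: cells; None means every library condition under its default report
    model_conditions: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if not self.observers:
            raise ValueError("need at least one observer")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if isinstance(self.condition_probs, str):
            if self.condition_probs != "model":
                raise ValueError("condition_probs must be a mapping or 'model'")
        else:
            for key, p in self.condition_probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability for {key} outside [0, 1]")

    @classmethod
    def uniform(
        cls,
        n_observers: int,
        condition_probs: Mapping[tuple[str, str], float] | str,
        lapse_rate: float = 0.02,
        T_window_ms: float = 425.0,
        **kwargs,
    ) -> "CohortSpec":
        """Cohort of identical observers O01..Onn."""
        observers = tuple(
            ObserverProfile(f"O{i + 1:02d}", T_window_ms, lapse_rate)
            for i in range(n_observers)
        )
        return cls(observers=observers, condition_probs=condition_probs, **kwargs)


def _model_probability(
    condition: str, report: Instruction, profile: ObserverProfile,
    spec: CohortSpec, params: ModelParams, net: DecisionNetworkParams,
) -> float:
    est = simulate_condition(
        condition,
        params.with_window(profile.T_window_ms),
        net,
        n_trials=spec.model_trials,
        seed=spec.seed,
        report=report,
    )
    return est.dominance / 100.0


def generate_cohort(
    spec: CohortSpec,
    params: ModelParams | None = None,
    net: DecisionNetworkParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort.

    Returns ``(summary, trials)``: ``summary`` has one row per
    (observer, condition, report) with the realized dominance, in the
    schema the analysis module consumes; ``trials`` holds the
    underlying binary responses.  Each response is "in accordance"
    with probability p*(1-lapse) + lapse/2.
    """
    params = params or ModelParams()
    net = net or DecisionNetworkParams()
    rng = np.random.default_rng(spec.seed)

    if isinstance(spec.condition_probs, str):
        cells = None  # resolved per observer below
    else:
        cells = list(spec.condition_probs.items())

    summary_rows = []
    trial_frames = []
    for profile in spec.observers:
        if cells is None:
            from .conditions import condition_library

            if spec.model_conditions is not None:
                keys = list(spec.model_conditions)
            else:
                keys = [
                    (name, cond.instruction.value)
                    for name, cond in condition_library().items()
                ]
            probs = {
                key: _model_probability(
                    key[0], Instruction(key[1]), profile, spec, params, net
                )
                for key in keys
            }
            items = probs.items()
        else:
            items = cells
        for (condition, report), p in items:
            p_eff = p * (1.0 - profile.lapse_rate) + 0.5 * profile.lapse_rate
            responses = rng.random(spec.trials_per_condition) < p_eff
            summary_rows.append(
                {
                    "observer_id": profile.observer_id,
                    "condition": condition,
                    "report": report if isinstance(report, str) else report.value,
                    "dominance": 100.0 * responses.mean(),
                    "n_trials": spec.trials_per_condition,
                }
            )
            trial_frames.append(
                pd.DataFrame(
                    {
                        "observer_id": profile.observer_id,
                        "condition": condition,
                        "report": report if isinstance(report, str) else report.value,
                        "trial": np.arange(spec.trials_per_condition),
                        "in_accordance": responses,
                    }
                )
            )
    summary = pd.DataFrame(summary_rows)
    trials = pd.concat(trial_frames, ignore_index=True)
    return summary, trials


@dataclass(frozen=True)
class ExclusionRule:
    """Prerequisite-consistency exclusion.

    An observer is excluded when dominance in ``condition_a`` indicates
    no integration (<= ``threshold_a``) while ``condition_b`` does not
    indicate flank dominance (> ``threshold_b``): the two prerequisite
    conditions contradict each other, so the boundary conditions of the
    main manipulation are not met for that observer.
    """

    condition_a: str = "V-AV8"
    condition_b: str = "V-AV12"
    threshold_a: float = 35.0
    threshold_b: float = 35.0


def exclusion_filter(
    summary: pd.DataFrame, rules: list[ExclusionRule] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply prerequisite exclusion rules to an observer-summary table.

    Returns ``(retained, log)``; the log has one row per excluded
    observer and rule.  An empty rule list retains everyone.  A rule
    whose prerequisite conditions are absent from the table is an
    error.
    """
    if rules is None:
        rules = []
    excluded: dict[str, list[str]] = {}
    for rule in rules:
        for cond in (rule.condition_a, rule.condition_b):
            if not (summary["condition"] == cond).any():
                raise ValueError(f"exclusion rule needs condition {cond!r} in table")
        dom = summary.pivot_table(
            index="observer_id", columns="condition", values="dominance",
            aggfunc="mean",
        )
        mask = (dom[rule.condition_a] <= rule.threshold_a) & (
            dom[rule.condition_b] > rule.threshold_b
        )
        for obs in dom.index[mask]:
            excluded.setdefault(obs, []).append(
                f"{rule.condition_a} <= {rule.threshold_a} "
                f"and {rule.condition_b} > {rule.threshold_b}"
            )
    log = pd.DataFrame(
        [
            {"observer_id": obs, "rule": reason}
            for obs, reasons in excluded.items()
            for reason in reasons
        ],
        columns=["observer_id", "rule"],
    )
    retained = summary[~summary["observer_id"].isin(excluded)].reset_index(drop=True)
    return retained, log
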