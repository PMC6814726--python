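"""YAML parameter files.

Schema: top-level keys ``tau``, ``c``, ``sigma``, ``mu0``,
``T_readout_ms``, ``evidence_scale`` (stage-1/readout parameters) and
an optional ``network`` section whose keys are the
``DecisionNetworkParams`` field names.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .decision import DecisionNetworkParams
from .memory import ModelParams

__all__ = ["load_params", "save_params"]

_MODEL_KEYS = ("tau", "c", "sigma", "mu0", "T_readout_ms", "evidence_scale")


def save_params(
    path: str | Path,
    params: ModelParams | None = None,
    net: DecisionNetworkParams | None = None,
) -> None:
    params = params or ModelParams()
    net = net or DecisionNetworkParams()
    doc = {k: getattr(params, k) for k in _MODEL_KEYS}
    doc["network"] = dataclasses.asdict(net)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_params(path: str | Path) -> tuple[ModelParams, DecisionNetworkParams]:
    doc = yaml.safe_load(Path(path).read_text())
    unknown = set(doc) - set(_MODEL_KEYS) - {"network"}
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    params = ModelParams(**{k: doc[k] for k in _MODEL_KEYS if k in doc})
    net = DecisionNetworkParams(**doc.get("network", {}))
    return params, net
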