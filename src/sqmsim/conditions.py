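"""Library of SQM experimental conditions.

Condition names follow the field's notation: "V" is a lone central
vernier, "AV" a lone flank anti-vernier, "V-AVn"/"V-PVn" a central
vernier plus an anti-/pro-vernier in flanking frame n.  "PVm-AVn" has
no central offset.  "C1".."C5" are the extended 20-pair
diverging-then-converging sequences in which groups of offsets are
placed before and/or after the first integration window.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .stimulus import ConditionSpec, Instruction, Reference, Variant

__all__ = ["condition_library", "get_condition", "library_to_yaml", "library_from_yaml"]

#: Flank frames probed in the first experiment's V-AV / V-PV series.
PROBED_FRAMES = (1, 2, 3, 5, 7, 11, 14)

_N_PAIRS_CLASSIC = 18
_N_PAIRS_EXTENDED = 20


def _classic(name, offsets, reference=Reference.CENTRAL,
             instruction=Instruction.NAIVE) -> ConditionSpec:
    return ConditionSpec(
        name=name,
        offsets=offsets,
        n_pairs=_N_PAIRS_CLASSIC,
        variant=Variant.DIVERGING,
        instruction=instruction,
        reference=reference,
    )


def _extended(name, offsets) -> ConditionSpec:
    return ConditionSpec(
        name=name,
        offsets=offsets,
        n_pairs=_N_PAIRS_EXTENDED,
        variant=Variant.DIVERGING_THEN_CONVERGING,
        instruction=Instruction.R1,
        reference=Reference.FIRST,
    )


def condition_library() -> dict[str, ConditionSpec]:
    """All conditions of the four experiments, keyed by name."""
    lib: dict[str, ConditionSpec] = {}

    # Single-offset calibration conditions.  The lone anti-vernier is
    # placed in frame 5, a representative mid-stream position; its
    # dominance is expressed against the pro direction, so a perfectly
    # reported AV sits near 25%.
    lib["V"] = _classic("V", {0: 1})
    lib["AV"] = _classic("AV", {5: -1})

    # Central vernier plus one flank vernier at a probed frame.
    for n in PROBED_FRAMES:
        lib[f"V-PV{n}"] = _classic(f"V-PV{n}", {0: 1, n: 1})
        lib[f"V-AV{n}"] = _classic(f"V-AV{n}", {0: 1, n: -1})

    # Window-boundary probes: frame 8 (330 ms) falls in the first
    # 425-ms window, frame 12 (490 ms) in the second.
    lib["V-AV8"] = _classic("V-AV8", {0: 1, 8: -1}, instruction=Instruction.R2)
    lib["V-AV12"] = _classic("V-AV12", {0: 1, 12: -1}, instruction=Instruction.R2)
    lib["V-AV8-PV12"] = _classic("V-AV8-PV12", {0: 1, 8: -1, 12: 1})

    # No central offset: tests whether the first window starts with
    # stimulus onset rather than with the first offset.
    lib["PV8-PV12"] = _classic("PV8-PV12", {8: 1, 12: 1}, reference=Reference.FIRST)
    lib["PV8-AV12"] = _classic("PV8-AV12", {8: 1, 12: -1}, reference=Reference.FIRST)
    lib["PV1-AV5"] = _classic("PV1-AV5", {1: 1, 5: -1}, reference=Reference.FIRST)

    # Extended 20-pair diverging-then-converging sequences.  Offsets
    # before the 450-ms boundary sit in frames 1, 5 and 8 (two
    # pro-verniers balancing one anti-vernier); offsets after it in
    # frames 12, 15 and 19 (two anti-verniers balancing one
    # pro-vernier).
    early = {1: 1, 5: -1, 8: 1}
    late = {12: -1, 15: 1, 19: -1}
    lib["C1"] = _extended("C1", dict(early))
    lib["C2"] = _extended("C2", dict(late))
    lib["C3"] = _extended("C3", {**early, 15: 1})
    lib["C4"] = _extended("C4", {5: -1, **late})
    lib["C5"] = _extended("C5", {**early, **late})
    return lib


def get_condition(name: str) -> ConditionSpec:
    lib = condition_library()
    try:
        return lib[name]
    except KeyError:
        raise KeyError(
            f"unknown condition {name!r}; known: {', '.join(sorted(lib))}"
        ) from None


def library_to_yaml(path: str | Path) -> None:
    """Serialize the condition library to a human-readable YAML file."""
    records = {
        name: {
            "offsets": {int(k): int(v) for k, v in spec.offsets.items()},
            "n_pairs": spec.n_pairs,
            "variant": spec.variant.value,
            "instruction": spec.instruction.value,
            "reference": spec.reference.value,
        }
        for name, spec in condition_library().items()
    }
    Path(path).write_text(yaml.safe_dump(records, sort_keys=True))


def library_from_yaml(path: str | Path) -> dict[str, ConditionSpec]:
    records = yaml.safe_load(Path(path).read_text())
    return {
        name: ConditionSpec(
            name=name,
            offsets={int(k): int(v) for k, v in rec["offsets"].items()},
            n_pairs=int(rec["n_pairs"]),
            variant=Variant(rec["variant"]),
            instruction=Instruction(rec["instruction"]),
            reference=Reference(rec["reference"]),
        )
        for name, rec in records.items()
    }
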