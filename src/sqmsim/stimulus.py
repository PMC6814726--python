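"""Sequential metacontrast (SQM) stimulus model.

The SQM presents a central vertical line followed by pairs of flanking
lines drawn one after the other, further and further away from the
center, eliciting a percept of two motion streams.  Any line may be a
vernier: its lower segment is horizontally offset relative to the upper
one.  The model cares only about timing and offset *direction*
(pro-vernier = +1, anti-vernier = -1, aligned = 0); offset magnitude in
arcmin is metadata.

Timing convention: every line is shown for 20 ms, the inter-stimulus
interval after the central line is 30 ms, and all subsequent ISIs are
20 ms, so flanking frame n (n >= 1) starts at 50 + 40*(n-1) ms.  All
stimulus-level times are exact integer milliseconds.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LINE_DURATION_MS",
    "FIRST_ISI_MS",
    "ISI_MS",
    "FLANK_SPACING_ARCMIN",
    "Variant",
    "Stream",
    "Instruction",
    "Reference",
    "Geometry",
    "LineElement",
    "PiecewiseConstant",
    "StimulusSequence",
    "ConditionSpec",
    "frame_onset",
    "build_sequence",
    "element_signal",
    "sequence_to_table",
]

LINE_DURATION_MS = 20
FIRST_ISI_MS = 30
ISI_MS = 20

#: Gap between neighbouring line eccentricities.  The printed per-gap
#: value is rounded to 3.3', but the stated separations (frame 8 to 12:
#: 13.3' over 4 gaps; center to frame 8: 26.7' over 8 gaps) require
#: 3.33' per gap.
FLANK_SPACING_ARCMIN = 10.0 / 3.0


class Variant(str, enum.Enum):
    """Motion-stream geometry of the sequence."""

    DIVERGING = "diverging"
    DIVERGING_THEN_CONVERGING = "diverging_then_converging"


class Stream(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Instruction(str, enum.Enum):
    """Report instruction given to the observer.

    NAIVE observers report the single perceived offset; R1/R2 instruct
    a report of the first/second presented vernier.
    """

    NAIVE = "naive"
    R1 = "R1"
    R2 = "R2"


class Reference(str, enum.Enum):
    """Which vernier defines 'dominance in accordance'."""

    CENTRAL = "central_vernier"
    FIRST = "first_vernier"
    SECOND = "second_vernier"


#: Frame at which the diverging-then-converging variant reverses its
#: motion direction.
DIRECTION_SWITCH_FRAME = 10


def frame_onset(frame_index: int) -> int:
    """Onset time in ms of a frame.

    Frame 0 is the central line (onset 0); flanking frame n >= 1 starts
    at 50 + 40*(n-1) ms (20 ms central line, 30 ms first ISI, then
    20 ms lines separated by 20 ms ISIs).

    >>> frame_onset(7)
    290
    """
    if frame_index < 0:
        raise ValueError(f"frame_index must be >= 0, got {frame_index}")
    if frame_index == 0:
        return 0
    return (
        LINE_DURATION_MS
        + FIRST_ISI_MS
        + (frame_index - 1) * (LINE_DURATION_MS + ISI_MS)
    )


@dataclass(frozen=True)
class Geometry:
    """Spatial layout of a sequence (eccentricities and line lengths).

    Lengths and eccentricities are in arcmin.  ``flank_length`` may be a
    constant (later experiments used 20' lines throughout) or ``None``,
    in which case lengths grow from ``first_flank_length`` by
    ``flank_length_increment`` per frame, as in the classic SQM.
    """

    flank_spacing: float = FLANK_SPACING_ARCMIN
    central_length: float = 10.0
    first_flank_length: float = 11.7
    flank_length_increment: float = 1.7
    flank_length: float | None = None

    @classmethod
    def growing(cls) -> "Geometry":
        """Growing flank lengths (11.7' + 1.7' per frame)."""
        return cls()

    @classmethod
    def constant(cls, length: float = 20.0) -> "Geometry":
        """Constant flank length (20' by default)."""
        return cls(central_length=20.0, flank_length=length)

    def length_of(self, frame: int) -> float:
        if frame == 0:
            return self.central_length
        if self.flank_length is not None:
            return self.flank_length
        return self.first_flank_length + self.flank_length_increment * (frame - 1)


@dataclass(frozen=True)
class LineElement:
    """One line of the SQM.

    ``location_id`` indexes the retinal position: 0 is the center, +n
    the n-th flank of the right stream, -n the n-th flank of the left
    stream.  ``offset_sign`` is +1 for a pro-vernier, -1 for an
    anti-vernier, 0 for an aligned line; ``offset_size`` (arcmin) is
    carried as metadata only and never enters the model.
    """

    location_id: int
    onset: int
    duration: int
    eccentricity: float
    length: float
    offset_sign: int
    offset_size: float = 0.0

    def __post_init__(self) -> None:
        if self.offset_sign not in (-1, 0, 1):
            raise ValueError(f"offset_sign must be -1, 0 or +1, got {self.offset_sign}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.eccentricity < 0:
            raise ValueError("eccentricity must be >= 0")

    @property
    def offset_end(self) -> int:
        return self.onset + self.duration


@dataclass(frozen=True)
class PiecewiseConstant:
    """Piecewise-constant signal over time (ms).

    ``edges`` are k+1 increasing breakpoints; ``values`` are the k
    constant levels on the half-open intervals [edges[i], edges[i+1]).
    The signal is 0 outside [edges[0], edges[-1]).
    """

    edges: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.edges) != len(self.values) + 1:
            raise ValueError("need len(edges) == len(values) + 1")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    def __call__(self, t_ms: float) -> float:
        i = np.searchsorted(self.edges, t_ms, side="right") - 1
        if i < 0 or i >= len(self.values):
            return 0.0
        return float(self.values[i])

    def segments(self) -> list[tuple[float, float, float]]:
        """(start_ms, end_ms, value) triples."""
        return [
            (self.edges[i], self.edges[i + 1], self.values[i])
            for i in range(len(self.values))
        ]

    def abs_area_ms(self) -> float:
        """Integral of |signal| over time, in value*ms."""
        widths = np.diff(self.edges)
        return float(np.sum(widths * np.abs(self.values)))


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition.

    ``offsets`` maps frame index -> offset sign; frame 0 is the central
    line.  A name like "V-AV8-PV12" denotes a central vernier, an
    anti-vernier in frame 8 and a pro-vernier in frame 12.
    """

    name: str
    offsets: Mapping[int, int]
    n_pairs: int
    variant: Variant = Variant.DIVERGING
    instruction: Instruction = Instruction.NAIVE
    reference: Reference = Reference.CENTRAL
    attended_stream: Stream = Stream.LEFT

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        for frame, sign in self.offsets.items():
            if not 0 <= frame <= self.n_pairs:
                raise ValueError(
                    f"{self.name}: offset frame {frame} outside [0, {self.n_pairs}]"
                )
            if sign not in (-1, 0, 1):
                raise ValueError(f"{self.name}: offset sign {sign} not in {{-1,0,+1}}")

    def reference_sign(self, reference: Reference | None = None) -> int:
        """Offset sign of the reference vernier.

        CENTRAL falls back to +1 (the nominal pro direction) when the
        central line is not offset, so that dominance for flank-only
        conditions is still expressed against the pro direction.
        """
        ref = self.reference if reference is None else reference
        nonzero = {f: s for f, s in self.offsets.items() if s != 0}
        if ref is Reference.CENTRAL:
            return int(nonzero.get(0, 1)) or 1
        if not nonzero:
            return 1
        if ref is Reference.FIRST:
            return int(nonzero[min(nonzero)])
        return int(nonzero[max(nonzero)])


def _eccentricity(frame: int, variant: Variant, spacing: float) -> float:
    if frame == 0:
        return 0.0
    if variant is Variant.DIVERGING_THEN_CONVERGING and frame > DIRECTION_SWITCH_FRAME:
        return spacing * (2 * DIRECTION_SWITCH_FRAME - frame)
    return spacing * frame


def build_sequence(
    spec: ConditionSpec, geometry: Geometry | None = None
) -> "StimulusSequence":
    """Build the full stimulus of a condition.

    One central element plus 2*n_pairs flanking elements.  Offsets are
    applied to the central line and to the attended stream's flank at
    the frames named in ``spec.offsets``; the unattended stream is
    always aligned (integration does not cross streams).
    """
    geometry = geometry or Geometry.growing()
    attended_sign = -1 if spec.attended_stream is Stream.LEFT else 1
    elements = [
        LineElement(
            location_id=0,
            onset=0,
            duration=LINE_DURATION_MS,
            eccentricity=0.0,
            length=geometry.length_of(0),
            offset_sign=int(spec.offsets.get(0, 0)),
        )
    ]
    for n in range(1, spec.n_pairs + 1):
        onset = frame_onset(n)
        ecc = _eccentricity(n, spec.variant, geometry.flank_spacing)
        length = geometry.length_of(n)
        for side in (-1, 1):
            sign = int(spec.offsets.get(n, 0)) if side == attended_sign else 0
            elements.append(
                LineElement(
                    location_id=side * n,
                    onset=onset,
                    duration=LINE_DURATION_MS,
                    eccentricity=ecc,
                    length=length,
                    offset_sign=sign,
                )
            )
    return StimulusSequence(
        elements=tuple(elements),
        n_pairs=spec.n_pairs,
        variant=spec.variant,
        attended_stream=spec.attended_stream,
    )


@dataclass(frozen=True)
class StimulusSequence:
    elements: tuple[LineElement, ...]
    n_pairs: int
    variant: Variant
    attended_stream: Stream

    @property
    def duration_ms(self) -> int:
        """Total stimulus duration: offset of the last line."""
        return max(e.offset_end for e in self.elements)

    @property
    def attended_location_ids(self) -> tuple[int, ...]:
        """Center plus the attended stream's flank locations, in order."""
        sign = -1 if self.attended_stream is Stream.LEFT else 1
        return (0,) + tuple(sign * n for n in range(1, self.n_pairs + 1))

    def element_at(self, location_id: int) -> LineElement:
        for e in self.elements:
            if e.location_id == location_id:
                return e
        raise KeyError(f"no element at location {location_id}")


def element_signal(seq: StimulusSequence, location_id: int) -> PiecewiseConstant:
    """Feature signal stim(t) of one retinal location.

    +1 while a pro-vernier is shown there, -1 for an anti-vernier, 0
    otherwise (including aligned lines).
    """
    e = seq.element_at(location_id)
    return PiecewiseConstant(
        edges=(float(e.onset), float(e.offset_end)),
        values=(float(e.offset_sign),),
    )


def sequence_to_table(seq: StimulusSequence) -> pd.DataFrame:
    """Flat export of a sequence, one row per line element."""
    return pd.DataFrame(
        {
            "location_id": [e.location_id for e in seq.elements],
            "onset_ms": [e.onset for e in seq.elements],
            "duration_ms": [e.duration for e in seq.elements],
            "eccentricity_arcmin": [e.eccentricity for e in seq.elements],
            "length_arcmin": [e.length for e in seq.elements],
            "offset_sign": [e.offset_sign for e in seq.elements],
        }
    )
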