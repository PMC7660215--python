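"""TUG trial segmentation into six functional movement phases.

A Timed-Up-and-Go trial is sliced by seven annotated events into six
segments: Sit-to-Stand, Walk Pass 1, Turn 1, Walk Pass 2, Turn 2 and
Stand-to-Sit.  Events are inputs (manual annotation or simulator output);
no automatic gait-event detection is performed.  Slices are half-open
``[start, end)`` so adjacent segments never share a frame.

The two walk passes cover the same 3 m path in opposite directions and
are pooled into a single ``Walk(1and2)`` class for analysis, doubling the
per-trial sample count of that segment.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "TugEvents",
    "SegmentSlice",
    "SEGMENT_LABELS",
    "WALK_POOLED_LABEL",
    "ANALYSIS_SEGMENTS",
    "segment_trial",
    "combine_walk_passes",
]

SEGMENT_LABELS = ("SitToStand", "Walk1", "Turn1", "Walk2", "Turn2", "StandToSit")
WALK_POOLED_LABEL = "Walk(1and2)"
#: Segment classes used in the statistical analysis (walk passes pooled).
ANALYSIS_SEGMENTS = ("SitToStand", WALK_POOLED_LABEL, "Turn1", "Turn2", "StandToSit")


@dataclass(frozen=True)
class TugEvents:
    """The seven TUG event timestamps, in seconds, strictly increasing.

    lean_start            participant begins to lean forward (Sit-to-Stand onset)
    first_heel_strike     first heel strike (walking begins)
    pre_turn1_toe_off     final toe off before the first turn
    post_turn1_heel_strike  first heel strike out of the first turn
    pre_turn2_toe_off     final toe off before the second turn
    knee_bend_start       knees begin to bend to sit
    seated                participant seated upright (trial end)
    """

    lean_start: float
    first_heel_strike: float
    pre_turn1_toe_off: float
    post_turn1_heel_strike: float
    pre_turn2_toe_off: float
    knee_bend_start: float
    seated: float

    def __post_init__(self) -> None:
        names = [f.name for f in fields(self)]
        vals = [float(getattr(self, n)) for n in names]
        for (na, va), (nb, vb) in zip(zip(names, vals), zip(names[1:], vals[1:])):
            if not vb > va:
                raise ValueError(
                    f"TUG events must be strictly increasing: {nb}={vb} <= {na}={va}"
                )

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


@dataclass(frozen=True)
class SegmentSlice:
    """One labeled half-open time slice ``[start_s, end_s)`` of a trial."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if not self.end_s > self.start_s:
            raise ValueError(f"segment {self.label}: end must exceed start")

    def contains(self, t) -> "pd.Series | bool":
        """Membership mask for timestamp(s) ``t`` (half-open interval)."""
        return (t >= self.start_s) & (t < self.end_s)


def segment_trial(events: TugEvents) -> list[SegmentSlice]:
    """The six segment slices delimited by the seven TUG events."""
    e = events
    bounds = [
        ("SitToStand", e.lean_start, e.first_heel_strike),
        ("Walk1", e.first_heel_strike, e.pre_turn1_toe_off),
        ("Turn1", e.pre_turn1_toe_off, e.post_turn1_heel_strike),
        ("Walk2", e.post_turn1_heel_strike, e.pre_turn2_toe_off),
        ("Turn2", e.pre_turn2_toe_off, e.knee_bend_start),
        ("StandToSit", e.knee_bend_start, e.seated),
    ]
    return [SegmentSlice(lab, s, t) for lab, s, t in bounds]


def combine_walk_passes(records: pd.DataFrame, column: str = "segment") -> pd.DataFrame:
    """Pool the two walk passes into one ``Walk(1and2)`` segment class.

    Rows labeled ``Walk1`` or ``Walk2`` are relabeled; all other rows pass
    through unchanged.  With every trial contributing both passes the walk
    class holds twice as many samples as any other segment.
    """
    out = records.copy()
    out[column] = out[column].replace({"Walk1": WALK_POOLED_LABEL, "Walk2": WALK_POOLED_LABEL})
    return out
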