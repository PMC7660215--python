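"""Sensor roster: the eleven lower-body IMU placements and their segment roles.

Each placement is attached to one body segment (torso, thigh, shank, foot).
Joint angles are computed between every sensor on the segment above a joint
and every sensor on the segment below it, so the roster fixes both the
universe of placements and the deterministic ordering of sensor pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SensorPlacement",
    "SensorRoster",
    "DEFAULT_ROSTER",
    "SEGMENTS",
    "JOINTS",
]

#: Segment roles in proximal-to-distal order.
SEGMENTS = ("torso", "thigh", "shank", "foot")

#: joint -> (proximal segment, distal segment)
JOINTS = {
    "hip": ("torso", "thigh"),
    "knee": ("thigh", "shank"),
    "ankle": ("shank", "foot"),
}

# (name, segment, seated_tilt) in canonical roster order.  ``seated_tilt``
# records which way the segment pitches in the seated calibration pose
# (legs outstretched, trunk leaning back): the trunk pitches posteriorly,
# every leg segment pitches anteriorly.  The calibration cross products
# need this to orient the medial-lateral axis consistently.
_ROSTER_SPEC = (
    ("L4-L5", "torso", "backward"),
    ("Sacrum", "torso", "backward"),
    ("LAT", "thigh", "forward"),
    ("MLT", "thigh", "forward"),
    ("LLT", "thigh", "forward"),
    ("LPT", "thigh", "forward"),
    ("Shin", "shank", "forward"),
    ("MLS", "shank", "forward"),
    ("LLS", "shank", "forward"),
    ("Heel", "foot", "forward"),
    ("DFoot", "foot", "forward"),
)


@dataclass(frozen=True)
class SensorPlacement:
    """One anatomical sensor location and the body segment it tracks."""

    name: str
    segment: str
    seated_tilt: str = "forward"

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"unknown segment role {self.segment!r}")
        if self.seated_tilt not in ("forward", "backward"):
            raise ValueError(f"seated_tilt must be forward/backward, got {self.seated_tilt!r}")


@dataclass(frozen=True)
class SensorRoster:
    """An ordered collection of sensor placements.

    The default roster holds the eleven study locations: two torso
    (L4-L5, Sacrum), four thigh (LAT, MLT, LLT, LPT), three shank
    (Shin, MLS, LLS) and two foot (Heel, DFoot) sensors.
    """

    placements: tuple[SensorPlacement, ...] = field(
        default_factory=lambda: tuple(
            SensorPlacement(n, s, t) for n, s, t in _ROSTER_SPEC
        )
    )

    def __post_init__(self) -> None:
        names = [p.name for p in self.placements]
        if len(set(names)) != len(names):
            raise ValueError("duplicate placement names in roster")

    def __iter__(self):
        return iter(self.placements)

    def __len__(self) -> int:
        return len(self.placements)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.placements)

    def get(self, name: str) -> SensorPlacement:
        for p in self.placements:
            if p.name == name:
                return p
        raise KeyError(f"placement {name!r} not in roster")

    def on_segment(self, segment: str) -> tuple[SensorPlacement, ...]:
        """Placements on one segment, in roster order."""
        if segment not in SEGMENTS:
            raise ValueError(f"unknown segment role {segment!r}")
        return tuple(p for p in self.placements if p.segment == segment)

    def drop(self, names) -> "SensorRoster":
        """Roster without the given placements (sensor dropout)."""
        names = set(names)
        unknown = names - set(self.names)
        if unknown:
            raise KeyError(f"cannot drop unknown placements {sorted(unknown)}")
        return SensorRoster(tuple(p for p in self.placements if p.name not in names))


DEFAULT_ROSTER = SensorRoster()
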