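"""Sagittal joint angles between sensor pairs, and projected reference angles.

For every joint the flexion/extension angle is measured between a sensor
on the segment above and a sensor on the segment below.  The distal SI
axis is projected into the proximal segment's coordinate system and the
angle read off with the two-argument arctangent of its AP and SI
components, so the value is quadrant-correct beyond +/-90 deg (deep knee
flexion during sit-to-stand exceeds 90 deg, where the plain arctan of the
component ratio would fold over).

Signs: flexion positive for hip and knee, dorsiflexion positive for the
ankle — a positive angle means the distal segment pitches anteriorly
relative to the proximal one.  Angles are zero whenever the segments are
parallel, in particular at the upright frame-one reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orientation import SegmentOrientationSeries
from .roster import JOINTS, SensorRoster

__all__ = [
    "JointAngleSeries",
    "enumerate_combinations",
    "flexion_angle",
    "reference_flexion",
]


@dataclass
class JointAngleSeries:
    """Flexion/extension angle time series for one sensor pair spanning a joint."""

    joint: str
    proximal: str
    distal: str
    timestamps: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.timestamps.shape != self.angles_deg.shape:
            raise ValueError("timestamps and angles length mismatch")
        if not np.all(np.isfinite(self.angles_deg)):
            raise ValueError("non-finite joint angles")

    def __len__(self) -> int:
        return len(self.timestamps)


def enumerate_combinations(roster: SensorRoster, joint: str) -> list[tuple[str, str]]:
    """All (proximal, distal) sensor pairs spanning ``joint``.

    Pairs are the cross product of the placements on the two adjacent
    segments, in deterministic roster order (proximal placements outer,
    distal inner).  The full eleven-sensor roster yields 8 hip, 12 knee
    and 6 ankle combinations.
    """
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}; expected one of {sorted(JOINTS)}")
    prox_seg, dist_seg = JOINTS[joint]
    return [
        (p.name, d.name)
        for p in roster.on_segment(prox_seg)
        for d in roster.on_segment(dist_seg)
    ]


def flexion_angle(
    prox: SegmentOrientationSeries,
    dist: SegmentOrientationSeries,
    joint: str = "",
) -> JointAngleSeries:
    """Sagittal angle of the distal SI axis in the proximal segment frame.

    Per frame the distal SI unit vector is expressed in the proximal
    SI/ML/AP basis and the angle computed as
    ``atan2(AP component, SI component)`` in degrees.  Zero when the
    segments are parallel; positive when the distal segment pitches
    anteriorly (flexion / dorsiflexion).
    """
    if prox.timestamps.shape != dist.timestamps.shape or not np.allclose(
        prox.timestamps, dist.timestamps, rtol=0.0, atol=1e-9
    ):
        raise ValueError("proximal and distal series must share timestamps")
    c_ap = np.einsum("ij,ij->i", dist.si, prox.ap)
    c_si = np.einsum("ij,ij->i", dist.si, prox.si)
    angles = np.degrees(np.arctan2(c_ap, c_si))
    return JointAngleSeries(
        joint=joint,
        proximal=prox.placement,
        distal=dist.placement,
        timestamps=prox.timestamps,
        angles_deg=angles,
    )


def reference_flexion(
    prox: SegmentOrientationSeries,
    dist: SegmentOrientationSeries,
    joint: str,
    *,
    degenerate_tol: float = 1e-6,
) -> np.ndarray:
    """Projected-axis reference angle, in the style of optical gait models.

    The distal segment's AP axis (for the foot: its long axis, which the
    anatomical frame carries as AP) is projected into the proximal
    segment's sagittal plane (the plane perpendicular to the proximal ML
    axis) and the signed angle to the proximal AP axis returned in
    degrees, flexion/dorsiflexion positive.

    Frames where the projection is degenerate (distal axis within
    ``degenerate_tol`` of perpendicular to the sagittal plane) inherit the
    previous frame's value; a leading degenerate frame yields 0.
    """
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}")
    axis = dist.ap
    ml_comp = np.einsum("ij,ij->i", axis, prox.ml)
    proj = axis - ml_comp[:, None] * prox.ml
    norms = np.linalg.norm(proj, axis=1)
    c_ap = np.einsum("ij,ij->i", proj, prox.ap)
    c_si = np.einsum("ij,ij->i", proj, prox.si)
    angles = np.degrees(np.arctan2(-c_si, c_ap))
    bad = norms < degenerate_tol
    if np.any(bad):
        angles = angles.copy()
        last = 0.0
        for i in range(angles.size):
            if bad[i]:
                angles[i] = last
            else:
                last = angles[i]
    return angles
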