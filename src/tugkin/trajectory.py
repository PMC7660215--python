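"""Analytic ground-truth joint-angle trajectories for a simulated TUG trial.

A trial is a piecewise-smooth curve per joint (hip, knee, ankle) built
from phase profiles: each of the six TUG phases carries, per joint, a
baseline transition (quintic smoothstep between start and end posture,
zero velocity at the boundaries) plus an optional oscillatory component
(gait cycles).  The defaults emulate a standard-height-chair TUG: rise
from ~80 deg hip / ~85 deg knee flexion, two 3 m walk passes of two gait
cycles each, two 180 deg turns about the vertical, and sitting back down.

Because capture starts with the subject standing upright (the frame-one
orientation reference), the trial timeline prepends a short standing hold
and a stand-to-sit preamble before the first annotated event.

Everything is C1-continuous by construction, and the curves are exact
closed forms, so downstream recovery can be tested to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segmentation import TugEvents

__all__ = [
    "JointPhaseParams",
    "PhaseProfile",
    "TrialTrajectory",
    "PHASE_ORDER",
    "JOINT_NAMES",
    "default_profiles",
    "build_trajectory",
]

PHASE_ORDER = ("sit_to_stand", "walk1", "turn1", "walk2", "turn2", "stand_to_sit")
JOINT_NAMES = ("hip", "knee", "ankle")

#: chain order used to integrate joint angles into segment pitches
_SEGMENT_CHAIN = ("pelvis", "thigh", "shank", "foot")


def smoothstep5(u: np.ndarray) -> np.ndarray:
    """Quintic smoothstep: 0->1 on [0,1] with zero 1st and 2nd derivative at ends."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (u * (6.0 * u - 15.0) + 10.0)


@dataclass(frozen=True)
class JointPhaseParams:
    """One joint's trajectory inside one phase.

    ``start_deg``/``end_deg`` anchor the baseline posture transition;
    ``amplitude_deg`` and ``cycles`` add an oscillation on top.  Waveform
    ``"sin2"`` is ``A sin^2(pi c u)`` (non-negative, attains exactly ``A``,
    C1 at the boundaries for integer ``cycles``); ``"sin"`` is a signed
    ``A sin(2 pi c u)`` tapered by ``sin^2(pi u)`` so boundaries stay C1
    (its extrema are then slightly below ``A``).
    """

    start_deg: float = 0.0
    end_deg: float = 0.0
    amplitude_deg: float = 0.0
    cycles: int = 0
    waveform: str = "sin2"

    def __post_init__(self) -> None:
        if self.waveform not in ("sin2", "sin"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.cycles < 0 or self.cycles != int(self.cycles):
            raise ValueError("cycles must be a non-negative integer")
        if self.amplitude_deg < 0:
            raise ValueError("amplitude must be non-negative")

    def __call__(self, u: np.ndarray) -> np.ndarray:
        """Angle (deg) at normalized phase time ``u`` in [0, 1]."""
        u = np.asarray(u, dtype=float)
        out = self.start_deg + (self.end_deg - self.start_deg) * smoothstep5(u)
        if self.amplitude_deg and self.cycles:
            if self.waveform == "sin2":
                out = out + self.amplitude_deg * np.sin(np.pi * self.cycles * u) ** 2
            else:
                out = out + (
                    self.amplitude_deg
                    * np.sin(2.0 * np.pi * self.cycles * u)
                    * np.sin(np.pi * u) ** 2
                )
        return out


@dataclass(frozen=True)
class PhaseProfile:
    """Duration and per-joint trajectory parameters of one TUG phase."""

    phase: str
    duration_s: float
    joints: dict = field(default_factory=dict)
    max_abs_deg: float = 130.0

    def __post_init__(self) -> None:
        if self.phase not in PHASE_ORDER:
            raise ValueError(f"unknown phase {self.phase!r}")
        if not self.duration_s > 0:
            raise ValueError(f"phase {self.phase}: duration must be positive")
        for j in self.joints:
            if j not in JOINT_NAMES:
                raise ValueError(f"unknown joint {j!r} in phase {self.phase}")
        for j, p in self.joints.items():
            peak = max(abs(p.start_deg), abs(p.end_deg)) + p.amplitude_deg
            if peak > self.max_abs_deg:
                raise ValueError(
                    f"phase {self.phase}, joint {j}: |angle| may reach {peak} deg, "
                    f"beyond the anatomical bound {self.max_abs_deg} deg"
                )

    def params(self, joint: str) -> JointPhaseParams:
        return self.joints.get(joint, JointPhaseParams())

    def with_duration(self, duration_s: float) -> "PhaseProfile":
        return replace(self, duration_s=duration_s)


#: Seated posture at the start of the TUG proper (deg, distal-forward positive).
SEATED_POSTURE = {"hip": 80.0, "knee": 85.0, "ankle": 5.0}


def default_profiles() -> list[PhaseProfile]:
    """Default six-phase TUG profile set (standard chair, two gait cycles/pass)."""
    sit = SEATED_POSTURE

    def trans(frm, to):
        return {
            j: JointPhaseParams(start_deg=frm[j], end_deg=to[j]) for j in JOINT_NAMES
        }

    stand = {j: 0.0 for j in JOINT_NAMES}

    def gait(hip_a, knee_a, ankle_a, cycles):
        return {
            "hip": JointPhaseParams(amplitude_deg=hip_a, cycles=cycles),
            "knee": JointPhaseParams(amplitude_deg=knee_a, cycles=cycles),
            "ankle": JointPhaseParams(amplitude_deg=ankle_a, cycles=cycles),
        }

    return [
        PhaseProfile("sit_to_stand", 1.5, trans(sit, stand)),
        PhaseProfile("walk1", 2.5, gait(30.0, 60.0, 15.0, 2)),
        PhaseProfile("turn1", 2.0, gait(20.0, 40.0, 10.0, 2)),
        PhaseProfile("walk2", 2.5, gait(30.0, 60.0, 15.0, 2)),
        PhaseProfile("turn2", 2.0, gait(20.0, 40.0, 10.0, 2)),
        PhaseProfile("stand_to_sit", 1.5, trans(stand, sit)),
    ]


class TrialTrajectory:
    """Continuous ground-truth kinematics of one simulated TUG trial.

    Exposes per-joint angles, per-segment sagittal pitches (built by
    chaining joint angles down the kinematic chain, with the pelvis
    pitching at a fraction of hip flexion), the shared heading rotation
    about the vertical during the turns, and the movement-engagement ramp
    used by the soft-tissue artifact model.
    """

    def __init__(
        self,
        profiles: list[PhaseProfile],
        *,
        stand_hold_s: float = 0.5,
        preamble_s: float = 2.0,
        settle_s: float = 0.5,
        pelvis_gain: float = 0.15,
        turn_deg: float = 180.0,
    ):
        names = [p.phase for p in profiles]
        if names != list(PHASE_ORDER):
            raise ValueError(
                f"phases must be exactly {list(PHASE_ORDER)} in order, got {names}"
            )
        for prev, nxt in zip(profiles[:-1], profiles[1:]):
            for j in JOINT_NAMES:
                a, b = prev.params(j).end_deg, nxt.params(j).start_deg
                if abs(a - b) > 1e-12:
                    raise ValueError(
                        f"discontinuity at {prev.phase}->{nxt.phase} for {j}: "
                        f"{a} deg vs {b} deg"
                    )
        if min(stand_hold_s, preamble_s, settle_s) <= 0:
            raise ValueError("preamble durations must be positive")
        self.profiles = list(profiles)
        self.stand_hold_s = float(stand_hold_s)
        self.preamble_s = float(preamble_s)
        self.settle_s = float(settle_s)
        self.pelvis_gain = float(pelvis_gain)
        self.turn_deg = float(turn_deg)

        t0 = stand_hold_s + preamble_s + settle_s
        bounds = [t0]
        for p in profiles:
            bounds.append(bounds[-1] + p.duration_s)
        #: start time of each of the six phases, plus the trial end
        self.phase_starts = dict(zip(PHASE_ORDER, bounds[:-1]))
        self.duration_s = bounds[-1]
        self._bounds = np.asarray(bounds)

    # -- events -----------------------------------------------------------
    @property
    def events(self) -> TugEvents:
        b = self._bounds
        return TugEvents(
            lean_start=b[0],
            first_heel_strike=b[1],
            pre_turn1_toe_off=b[2],
            post_turn1_heel_strike=b[3],
            pre_turn2_toe_off=b[4],
            knee_bend_start=b[5],
            seated=b[6],
        )

    # -- joint angles ------------------------------------------------------
    def joint_angle(self, joint: str, t: np.ndarray) -> np.ndarray:
        """Ground-truth angle of ``joint`` (deg) at time(s) ``t``."""
        if joint not in JOINT_NAMES:
            raise ValueError(f"unknown joint {joint!r}")
        t_in = np.asarray(t, dtype=float)
        t = np.atleast_1d(t_in)
        out = np.empty_like(t)

        start0 = self.profiles[0].params(joint).start_deg
        hold_end = self.stand_hold_s
        pre_end = hold_end + self.preamble_s

        # standing hold -> preamble transition to seated -> settle
        out[...] = 0.0
        pre = (t >= hold_end) & (t < pre_end)
        out[pre] = start0 * smoothstep5((t[pre] - hold_end) / self.preamble_s)
        out[(t >= pre_end) & (t < self._bounds[0])] = start0

        for p, a, b in zip(self.profiles, self._bounds[:-1], self._bounds[1:]):
            m = (t >= a) & (t < b)
            if np.any(m):
                out[m] = p.params(joint)((t[m] - a) / p.duration_s)
        last = t >= self._bounds[-1]
        out[last] = self.profiles[-1].params(joint)(1.0)
        return out[0] if t_in.ndim == 0 else out

    # -- segment pitches and heading --------------------------------------
    def segment_pitch(self, segment: str, t: np.ndarray) -> np.ndarray:
        """Sagittal pitch of a body segment (deg, anterior positive).

        The pelvis pitches at ``pelvis_gain`` times hip flexion; each more
        distal segment adds its joint's angle, so the measured angle
        between adjacent segments equals the ground-truth joint angle.
        """
        if segment == "torso":
            segment = "pelvis"
        if segment not in _SEGMENT_CHAIN:
            raise ValueError(f"unknown segment {segment!r}")
        hip = self.joint_angle("hip", t)
        pitch = self.pelvis_gain * hip
        if segment == "pelvis":
            return pitch
        pitch = pitch + hip
        if segment == "thigh":
            return pitch
        pitch = pitch + self.joint_angle("knee", t)
        if segment == "shank":
            return pitch
        return pitch + self.joint_angle("ankle", t)

    def heading(self, t: np.ndarray) -> np.ndarray:
        """Shared body heading about the vertical (deg): 0 -> 180 -> 360."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for phase in ("turn1", "turn2"):
            a = self.phase_starts[phase]
            d = self.profiles[PHASE_ORDER.index(phase)].duration_s
            out = out + self.turn_deg * smoothstep5((t - a) / d)
        return out

    def movement_ramp(self, t: np.ndarray) -> np.ndarray:
        """0 at the standing reference, rising to 1 over the preamble.

        Used to engage movement-induced mounting artifacts after the
        static frame-one reference.
        """
        t = np.asarray(t, dtype=float)
        return smoothstep5((t - self.stand_hold_s) / self.preamble_s)


def build_trajectory(profiles: list[PhaseProfile] | None = None, **kwargs) -> TrialTrajectory:
    """Build a :class:`TrialTrajectory` (default profiles if none given)."""
    if profiles is None:
        profiles = default_profiles()
    return TrialTrajectory(profiles, **kwargs)
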