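"""Synthetic TUG studies with known ground truth.

Generates complete multi-subject studies mirroring the measurement setup
the analysis assumes: per-sensor unit-quaternion streams at the IMU rate
(40 or 60 Hz), static calibration accelerometer frames for the standing
and seated poses, a reference joint-angle channel at the optical-capture
rate (100 or 120 Hz), TUG event annotations, and ground-truth angles.

World frame: right-handed, gravity 9.81 m/s^2 along -Z, X anterior at the
start.  Standing upright, every segment's anatomical axes are SI = +Z,
AP = +X, with ML completing the right-handed (SI, ML, AP) triad.  Segment
motion composes a shared heading rotation about the vertical (the turns)
with each segment's sagittal pitch from the trajectory chain.

Error structure (all per sensor, all optional):

* ``offset`` — movement-engaged mounting rotation.  Soft tissue and strap
  compliance deform the mount between the static standing reference and
  dynamic movement; the offset rotation ramps in smoothly during the
  stand-to-sit preamble and persists for the rest of the trial.  Because
  it is absent from the frame-one reference, it survives the frame-one
  alignment and appears downstream as joint-angle bias: a +d deg offset
  about the ML axis on one sensor biases that sensor's pairs by exactly
  +d deg (distal role) or -d deg (proximal role).
* ``static offset`` — a constant sensor-vs-segment mounting rotation,
  present during both calibration poses and the whole trial.  Two-pose
  calibration plus frame-one alignment cancel it exactly; it is included
  so that invariance can be exercised.
* ``jitter`` — per-frame white rotational noise (independent small random
  rotations, rotation-vector components i.i.d. N(0, sd^2)), zero during
  the static standing hold.
* ``accelerometer noise`` — additive white noise on calibration frames.
* ``reference noise`` — additive white angular noise on the reference
  channel (the optical system is a gold standard, not noiseless).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .angles import reference_flexion
from .orientation import QuaternionStream, SegmentOrientationSeries
from .roster import DEFAULT_ROSTER, SensorPlacement, SensorRoster
from .segmentation import TugEvents
from .trajectory import (
    JOINT_NAMES,
    PhaseProfile,
    TrialTrajectory,
    build_trajectory,
    default_profiles,
)

__all__ = [
    "StudyDesign",
    "MountingModel",
    "SyntheticTrial",
    "default_design",
    "default_mounts",
    "zero_mounts",
    "synthesize_sensor_stream",
    "generate_study",
]

GRAVITY = 9.81  # m/s^2, world -Z

#: anatomical-to-world axis matrix at upright standing (columns SI, ML, AP)
A0 = np.column_stack([(0.0, 0.0, 1.0), (0.0, -1.0, 0.0), (1.0, 0.0, 0.0)])

#: per-segment sagittal pitch (deg, anterior positive) in the seated
#: calibration pose: trunk leaning back, legs outstretched.
SEATED_CALIB_PITCH_DEG = {"torso": -20.0, "thigh": 80.0, "shank": 70.0, "foot": 30.0}


class ConfigurationError(ValueError):
    """Invalid study design or mounting configuration."""


@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic TUG study.

    The default mirrors the study bookkeeping: seven subjects, five
    performing three trials and two performing five (25 trials), IMUs at
    60 Hz (40 in part of the study) and the reference at 120 Hz (100 in
    part of the study).  ``dropout_sensors`` excludes placements either
    globally (a set of names) or per subject (mapping subject id -> names),
    emulating faulty recordings.
    """

    n_subjects: int = 7
    trials_per_subject: tuple = (3, 3, 3, 3, 3, 5, 5)
    imu_rate_hz: float = 60.0
    ref_rate_hz: float = 120.0
    dropout_sensors: object = None
    seed: int = 0
    duration_jitter: float = 0.1
    ref_noise_sd_deg: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("need at least one subject")
        object.__setattr__(self, "trials_per_subject", tuple(self.trials_per_subject))
        if len(self.trials_per_subject) != self.n_subjects:
            raise ConfigurationError("trials_per_subject length must equal n_subjects")
        if any(k < 1 for k in self.trials_per_subject):
            raise ConfigurationError("every subject needs at least one trial")
        if self.imu_rate_hz <= 0 or self.ref_rate_hz <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if not 0.0 <= self.duration_jitter < 1.0:
            raise ConfigurationError("duration_jitter must be in [0, 1)")
        if self.ref_noise_sd_deg < 0:
            raise ConfigurationError("reference noise sd must be non-negative")

    @property
    def n_trials(self) -> int:
        return int(sum(self.trials_per_subject))

    @property
    def subject_ids(self) -> tuple:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_subjects))

    def dropout_for(self, subject_id: str, roster: SensorRoster) -> frozenset:
        d = self.dropout_sensors
        if d is None:
            return frozenset()
        if isinstance(d, dict):
            names = frozenset(d.get(subject_id, ()))
        else:
            names = frozenset(d)
        unknown = names - set(roster.names)
        if unknown:
            raise ConfigurationError(f"dropout names not in roster: {sorted(unknown)}")
        return names


def _axis_rotvec(axis) -> np.ndarray:
    """Unit rotation axis in internal anatomical coordinates.

    String axes use the convention that a positive rotation about ``"ml"``
    pitches the sensed frame anteriorly (reads as extra flexion); vector
    input gives (si, ml, ap) components under the same convention.
    """
    basis = {"si": (1.0, 0.0, 0.0), "ml": (0.0, -1.0, 0.0), "ap": (0.0, 0.0, 1.0)}
    if isinstance(axis, str):
        if axis not in basis:
            raise ConfigurationError(f"offset axis must be si/ml/ap or 3-vector, got {axis!r}")
        return np.array(basis[axis])
    v = np.asarray(axis, dtype=float)
    if v.shape != (3,) or np.linalg.norm(v) == 0:
        raise ConfigurationError("offset axis vector must be a nonzero 3-vector")
    v = v / np.linalg.norm(v)
    return v[0] * np.array(basis["si"]) + v[1] * np.array(basis["ml"]) + v[2] * np.array(basis["ap"])


@dataclass(frozen=True)
class MountingModel:
    """Per-placement mounting and noise model (see module docstring)."""

    placement: str
    offset_axis: object = "ml"
    offset_deg: float = 0.0
    offset_subject_sd_deg: float = 0.0
    static_axis: object = "ml"
    static_deg: float = 0.0
    jitter_sd_deg: float = 0.0
    accel_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.jitter_sd_deg, self.accel_noise_sd, self.offset_subject_sd_deg) < 0:
            raise ConfigurationError("noise scales must be non-negative")
        _axis_rotvec(self.offset_axis)
        _axis_rotvec(self.static_axis)

    @property
    def offset_rotvec_rad(self) -> np.ndarray:
        return np.deg2rad(self.offset_deg) * _axis_rotvec(self.offset_axis)

    @property
    def static_rotation(self) -> Rotation:
        return Rotation.from_rotvec(np.deg2rad(self.static_deg) * _axis_rotvec(self.static_axis))


def zero_mounts(roster: SensorRoster = DEFAULT_ROSTER) -> dict:
    """Ideal mounting: no offsets, no noise (for identity/recovery tests)."""
    return {p.name: MountingModel(p.name) for p in roster}


def default_mounts(roster: SensorRoster = DEFAULT_ROSTER) -> dict:
    """Plausible per-location mounting errors and soft-tissue noise.

    Chosen once as a realistic operating point: a few degrees of
    movement-engaged offset, larger over soft tissue (posterior thigh,
    shoe-mounted heel) and smaller over bone (shin); jitter 1-2.5 deg.
    These are configurable placeholders, not estimates of any particular
    cohort.
    """
    table = {
        # name: (offset_deg about ml, between-subject offset sd, jitter_sd_deg)
        "L4-L5": (2.0, 1.5, 1.0),
        "Sacrum": (-1.5, 1.5, 1.0),
        "LAT": (2.0, 1.5, 1.2),
        "MLT": (-2.5, 2.0, 1.5),
        "LLT": (3.0, 1.5, 1.2),
        "LPT": (-5.0, 2.5, 2.5),
        "Shin": (-3.0, 1.0, 0.8),
        "MLS": (1.5, 1.5, 1.2),
        "LLS": (-1.5, 1.5, 1.2),
        "Heel": (4.0, 2.0, 2.0),
        "DFoot": (2.0, 1.5, 1.5),
    }
    return {
        p.name: MountingModel(
            p.name,
            offset_deg=table[p.name][0],
            offset_subject_sd_deg=table[p.name][1],
            jitter_sd_deg=table[p.name][2],
            accel_noise_sd=0.05,
        )
        for p in roster
    }


@dataclass
class SyntheticTrial:
    """One simulated TUG trial with ground truth.

    ``truth_angles``/``ref_angles`` are DataFrames (time_s, hip, knee,
    ankle) at the reference rate; ``segment_triads`` holds the true
    world-frame anatomical axes of each segment at the reference rate.
    """

    subject: str
    trial: int
    events: TugEvents
    sensor_streams: dict
    calib_standing: dict
    calib_seated: dict
    truth_angles: pd.DataFrame
    ref_angles: pd.DataFrame
    segment_triads: dict
    trajectory: TrialTrajectory
    imu_rate_hz: float
    ref_rate_hz: float


def _euler(axis: str, angles_deg) -> Rotation:
    """Single-axis Euler rotation(s); accepts scalar or (n,) arrays."""
    a = np.asarray(angles_deg, dtype=float)
    if a.ndim == 0:
        return Rotation.from_euler(axis, float(a), degrees=True)
    return Rotation.from_euler(axis, a.reshape(-1, 1), degrees=True)


def _segment_world_rotations(traj: TrialTrajectory, segment: str, t: np.ndarray) -> Rotation:
    """True segment rotation (anatomical axes -> world) at times ``t``."""
    pitch = traj.segment_pitch(segment, t)
    heading = traj.heading(t)
    return (
        _euler("z", heading) * _euler("y", pitch) * Rotation.from_matrix(A0)
    )


def synthesize_sensor_stream(
    traj: TrialTrajectory,
    placement: SensorPlacement,
    mount: MountingModel,
    rate_hz: float,
    rng: np.random.Generator,
    *,
    n_seated_frames: int = 50,
) -> tuple[QuaternionStream, np.ndarray, np.ndarray]:
    """Simulate one sensor: quaternion stream plus calibration accel frames.

    The stream covers the whole trial at ``rate_hz``; frame one is the
    upright standing reference.  Standing calibration frames are the
    samples of the standing hold; seated calibration frames come from a
    separate static pose with the study's seated pitches.
    """
    if rate_hz <= 0:
        raise ConfigurationError("IMU rate must be positive")
    t = np.arange(0.0, traj.duration_s, 1.0 / rate_hz)
    seg_rot = _segment_world_rotations(traj, placement.segment, t)

    ramp = traj.movement_ramp(t)
    offset = Rotation.from_rotvec(np.outer(ramp, mount.offset_rotvec_rad))
    jitter_vec = rng.normal(0.0, np.deg2rad(mount.jitter_sd_deg), size=(t.size, 3))
    jitter_vec[t < traj.stand_hold_s] = 0.0
    jitter = Rotation.from_rotvec(jitter_vec)

    sensor_rot = seg_rot * jitter * offset * mount.static_rotation
    q = sensor_rot.as_quat(scalar_first=True)
    stream = QuaternionStream(timestamps=t, q=q, placement=placement.name, rate_hz=rate_hz)

    g_world = np.array([0.0, 0.0, -GRAVITY])
    # standing pose: identical to the stream's static hold (no jitter/offset)
    stand_rot = Rotation.from_matrix(A0) * mount.static_rotation
    n_stand = max(1, int(round(traj.stand_hold_s * rate_hz)))
    calib_stand = np.tile(stand_rot.inv().apply(g_world), (n_stand, 1))
    calib_stand = calib_stand + rng.normal(0.0, mount.accel_noise_sd, size=calib_stand.shape)

    sit_pitch = SEATED_CALIB_PITCH_DEG[placement.segment]
    sit_rot = _euler("y", sit_pitch) * Rotation.from_matrix(A0) * mount.static_rotation
    calib_seated = np.tile(sit_rot.inv().apply(g_world), (n_seated_frames, 1))
    calib_seated = calib_seated + rng.normal(0.0, mount.accel_noise_sd, size=calib_seated.shape)

    return stream, calib_stand, calib_seated


def _truth_and_reference(
    traj: TrialTrajectory,
    ref_rate_hz: float,
    ref_noise_sd_deg: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    t = np.arange(0.0, traj.duration_s, 1.0 / ref_rate_hz)
    triads = {}
    for segment in ("torso", "thigh", "shank", "foot"):
        rot = _segment_world_rotations(traj, segment, t)
        mats = rot.as_matrix()
        triads[segment] = SegmentOrientationSeries(
            timestamps=t,
            si=mats[:, :, 0],
            ml=mats[:, :, 1],
            ap=mats[:, :, 2],
            placement=segment,
        )
    truth = pd.DataFrame({"time_s": t})
    ref = pd.DataFrame({"time_s": t})
    pairs = {"hip": ("torso", "thigh"), "knee": ("thigh", "shank"), "ankle": ("shank", "foot")}
    for joint in JOINT_NAMES:
        truth[joint] = traj.joint_angle(joint, t)
        prox, dist = pairs[joint]
        projected = reference_flexion(triads[prox], triads[dist], joint)
        ref[joint] = projected + rng.normal(0.0, ref_noise_sd_deg, size=t.size)
    return truth, ref, triads


def generate_study(
    design: StudyDesign,
    profiles: list[PhaseProfile] | None = None,
    mounts: dict | None = None,
    roster: SensorRoster = DEFAULT_ROSTER,
) -> list[SyntheticTrial]:
    """Generate all trials of a synthetic study, deterministically by seed.

    Per-trial randomness (phase-duration jitter, sensor jitter, noise) is
    drawn from independent child generators spawned from the design seed,
    so the output is byte-identical across runs with the same inputs.
    Dropout sensors are absent from ``sensor_streams`` of the affected
    subjects' trials.
    """
    if profiles is None:
        profiles = default_profiles()
    if mounts is None:
        mounts = zero_mounts(roster)
    missing = set(roster.names) - set(mounts)
    if missing:
        raise ConfigurationError(f"no MountingModel for placements {sorted(missing)}")

    root = np.random.SeedSequence(design.seed)
    subject_seqs = root.spawn(design.n_subjects)
    children = root.spawn(design.n_trials)
    trials: list[SyntheticTrial] = []
    k = 0
    for s_idx, (subject, n_trials) in enumerate(
        zip(design.subject_ids, design.trials_per_subject)
    ):
        dropped = design.dropout_for(subject, roster)
        # subject-level mounting realization: each subject's sensors sit at
        # their own offset around the location's typical value, constant
        # across that subject's trials (the source of within-subject
        # correlation the GEE models)
        s_rng = np.random.default_rng(subject_seqs[s_idx])
        subj_mounts = {}
        for placement in roster:
            m = mounts[placement.name]
            draw = s_rng.normal(0.0, 1.0)
            subj_mounts[placement.name] = (
                replace(m, offset_deg=m.offset_deg + draw * m.offset_subject_sd_deg)
                if m.offset_subject_sd_deg > 0
                else m
            )
        for trial_idx in range(1, n_trials + 1):
            rng = np.random.default_rng(children[k])
            k += 1
            scales = rng.uniform(
                1.0 - design.duration_jitter, 1.0 + design.duration_jitter, size=len(profiles)
            )
            trial_profiles = [
                p.with_duration(p.duration_s * s) for p, s in zip(profiles, scales)
            ]
            traj = build_trajectory(trial_profiles)
            truth, ref, triads = _truth_and_reference(
                traj, design.ref_rate_hz, design.ref_noise_sd_deg, rng
            )
            streams: dict = {}
            calib_stand: dict = {}
            calib_seat: dict = {}
            for placement in roster:
                if placement.name in dropped:
                    continue
                stream, cs, cq = synthesize_sensor_stream(
                    traj, placement, subj_mounts[placement.name], design.imu_rate_hz, rng
                )
                streams[placement.name] = stream
                calib_stand[placement.name] = cs
                calib_seat[placement.name] = cq
            trials.append(
                SyntheticTrial(
                    subject=subject,
                    trial=trial_idx,
                    events=traj.events,
                    sensor_streams=streams,
                    calib_standing=calib_stand,
                    calib_seated=calib_seat,
                    truth_angles=truth,
                    ref_angles=ref,
                    segment_triads=triads,
                    trajectory=traj,
                    imu_rate_hz=design.imu_rate_hz,
                    ref_rate_hz=design.ref_rate_hz,
                )
            )
    return trials


def default_design(**overrides) -> StudyDesign:
    """The study's default design (7 subjects, 25 trials)."""
    return StudyDesign(**overrides)
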