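"""End-to-end orchestration: simulate -> calibrate -> angles -> errors -> stats.

Stage functions operate on in-memory :class:`~tugkin.simulate.SyntheticTrial`
objects (or equivalent data loaded from disk by :mod:`tugkin.studyio`) and
compose into :func:`run_study`, which turns a study design into the
long-format error table, and :func:`analyze_study`, which pools the walk
passes and fits the per-joint GEE comparisons.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import errors as err
from .angles import JointAngleSeries, enumerate_combinations, flexion_angle
from .calibration import CalibrationFrame, build_calibration_frame, gravity_vector
from .gee import analyze_joint
from .orientation import SegmentOrientationSeries, globalize_series
from .roster import DEFAULT_ROSTER, JOINTS, SensorRoster
from .segmentation import combine_walk_passes, segment_trial
from .simulate import StudyDesign, SyntheticTrial, generate_study

__all__ = [
    "calibrate_trial",
    "globalize_trial",
    "trial_pair_angles",
    "study_error_table",
    "run_study",
    "analyze_study",
]

log = logging.getLogger("tugkin")


def calibrate_trial(trial: SyntheticTrial, roster: SensorRoster = DEFAULT_ROSTER) -> dict:
    """Two-pose calibration frame for every sensor present in the trial."""
    frames: dict[str, CalibrationFrame] = {}
    for name, stand in trial.calib_standing.items():
        placement = roster.get(name)
        frames[name] = build_calibration_frame(
            gravity_vector(stand),
            gravity_vector(trial.calib_seated[name]),
            seated_tilt=placement.seated_tilt,
            placement=name,
        )
    return frames


def globalize_trial(trial: SyntheticTrial, frames: dict) -> dict:
    """Common-frame orientation series for every calibrated sensor."""
    out: dict[str, SegmentOrientationSeries] = {}
    for name, frame in frames.items():
        out[name] = globalize_series(frame, trial.sensor_streams[name])
    return out


def trial_pair_angles(
    trial: SyntheticTrial,
    series: dict,
    roster: SensorRoster = DEFAULT_ROSTER,
) -> list[JointAngleSeries]:
    """Flexion angles for every sensor pair available in this trial.

    Pairs are enumerated on the roster restricted to the sensors actually
    present (dropout removes every pair involving a missing sensor).
    """
    present = roster.drop(set(roster.names) - set(series))
    angle_series = []
    for joint in JOINTS:
        for prox, dist in enumerate_combinations(present, joint):
            angle_series.append(flexion_angle(series[prox], series[dist], joint=joint))
    return angle_series


def study_error_table(
    trials: list[SyntheticTrial], roster: SensorRoster = DEFAULT_ROSTER
) -> pd.DataFrame:
    """Run calibration, orientation, angles and error metrics over a study."""

    def inputs():
        for trial in trials:
            frames = calibrate_trial(trial, roster)
            series = globalize_trial(trial, frames)
            angle_series = trial_pair_angles(trial, series, roster)
            slices = segment_trial(trial.events)
            yield trial.subject, trial.trial, angle_series, trial.ref_angles, slices

    table = err.build_error_table(inputs())
    log.info("error table: %d records from %d trials", len(table), len(trials))
    return table


def run_study(
    design: StudyDesign,
    profiles=None,
    mounts=None,
    roster: SensorRoster = DEFAULT_ROSTER,
) -> tuple[list[SyntheticTrial], pd.DataFrame]:
    """Simulate a study and compute its error table."""
    trials = generate_study(design, profiles=profiles, mounts=mounts, roster=roster)
    return trials, study_error_table(trials, roster)


def analyze_study(
    records: pd.DataFrame, roster: SensorRoster = DEFAULT_ROSTER
) -> dict[str, pd.DataFrame]:
    """Pool walk passes and fit the per-joint GEE sensor-pair comparisons."""
    pooled = combine_walk_passes(records)
    results = {}
    for joint in JOINTS:
        pair_order = [f"{p}/{d}" for p, d in enumerate_combinations(roster, joint)]
        present = pooled[pooled["joint"] == joint]
        observed = set((present["proximal"] + "/" + present["distal"]).unique())
        order = [p for p in pair_order if p in observed]
        results[joint] = analyze_joint(pooled, joint, pair_order=order or None)
        log.info("GEE %s: %d cells", joint, len(results[joint]))
    return results
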