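"""Plain-text study artifacts: CSV/JSON readers and writers.

Layout of a study directory written by :func:`write_study`::

    manifest.json                   subjects, trials, rates, dropout, seed
    S01_t1/
        events.json                 the seven TUG event timestamps
        truth_angles.csv            time_s, hip, knee, ankle (deg, ref rate)
        ref_angles.csv              same layout, reference channel
        quat_<placement>.csv        time_s, qw, qx, qy, qz (scalar-first)
        calib_standing_<placement>.csv   time-less ax, ay, az frames (m/s^2)
        calib_seated_<placement>.csv
    ...

Calibration frames go to JSON via :func:`write_calibration_frames`; angle
tables, error tables and summary tables are plain CSV.  All schemas carry
a version tag in the manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .calibration import CalibrationFrame
from .orientation import QuaternionStream
from .segmentation import TugEvents

__all__ = [
    "write_study",
    "read_trial",
    "read_manifest",
    "write_calibration_frames",
    "read_calibration_frames",
    "write_angle_table",
    "read_angle_table",
]

SCHEMA_VERSION = "1"


def _trial_dirname(subject: str, trial: int) -> str:
    return f"{subject}_t{trial}"


def write_study(trials, out_dir, design=None) -> Path:
    """Write all trials and a manifest to ``out_dir``; returns the path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for tr in trials:
        d = out / _trial_dirname(tr.subject, tr.trial)
        d.mkdir(exist_ok=True)
        (d / "events.json").write_text(json.dumps(tr.events.as_dict(), indent=1))
        tr.truth_angles.to_csv(d / "truth_angles.csv", index=False)
        tr.ref_angles.to_csv(d / "ref_angles.csv", index=False)
        for name, stream in tr.sensor_streams.items():
            df = pd.DataFrame(
                {
                    "time_s": stream.timestamps,
                    "qw": stream.q[:, 0],
                    "qx": stream.q[:, 1],
                    "qy": stream.q[:, 2],
                    "qz": stream.q[:, 3],
                }
            )
            df.to_csv(d / f"quat_{name}.csv", index=False)
            pd.DataFrame(tr.calib_standing[name], columns=["ax", "ay", "az"]).to_csv(
                d / f"calib_standing_{name}.csv", index=False
            )
            pd.DataFrame(tr.calib_seated[name], columns=["ax", "ay", "az"]).to_csv(
                d / f"calib_seated_{name}.csv", index=False
            )
        index.append(
            {
                "subject": tr.subject,
                "trial": tr.trial,
                "dir": d.name,
                "sensors": sorted(tr.sensor_streams),
                "imu_rate_hz": tr.imu_rate_hz,
                "ref_rate_hz": tr.ref_rate_hz,
            }
        )
    manifest = {"schema_version": SCHEMA_VERSION, "trials": index}
    if design is not None:
        manifest["design"] = {
            "n_subjects": design.n_subjects,
            "trials_per_subject": list(design.trials_per_subject),
            "imu_rate_hz": design.imu_rate_hz,
            "ref_rate_hz": design.ref_rate_hz,
            "seed": design.seed,
            "dropout_sensors": _jsonable_dropout(design.dropout_sensors),
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _jsonable_dropout(d):
    if d is None:
        return None
    if isinstance(d, dict):
        return {k: sorted(v) for k, v in d.items()}
    return sorted(d)


def read_manifest(study_dir) -> dict:
    path = Path(study_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {study_dir}")
    return json.loads(path.read_text())


def read_trial(study_dir, entry: dict) -> SimpleNamespace:
    """Load one manifest entry back into arrays/streams.

    Returns an object with attributes subject, trial, events,
    sensor_streams, calib_standing, calib_seated, ref_angles,
    truth_angles — the subset of
    :class:`~tugkin.simulate.SyntheticTrial` the analysis needs.
    """
    d = Path(study_dir) / entry["dir"]
    events = TugEvents(**json.loads((d / "events.json").read_text()))
    streams, stand, seated = {}, {}, {}
    for name in entry["sensors"]:
        q = pd.read_csv(d / f"quat_{name}.csv")
        streams[name] = QuaternionStream(
            timestamps=q["time_s"].to_numpy(),
            q=q[["qw", "qx", "qy", "qz"]].to_numpy(),
            placement=name,
            rate_hz=entry["imu_rate_hz"],
        )
        stand[name] = pd.read_csv(d / f"calib_standing_{name}.csv").to_numpy()
        seated[name] = pd.read_csv(d / f"calib_seated_{name}.csv").to_numpy()
    return SimpleNamespace(
        subject=entry["subject"],
        trial=entry["trial"],
        events=events,
        sensor_streams=streams,
        calib_standing=stand,
        calib_seated=seated,
        truth_angles=pd.read_csv(d / "truth_angles.csv"),
        ref_angles=pd.read_csv(d / "ref_angles.csv"),
    )


def write_calibration_frames(frames: dict, path) -> None:
    """Per-sensor SI/ML/AP triplets as JSON."""
    payload = {
        name: {"si": f.si.tolist(), "ml": f.ml.tolist(), "ap": f.ap.tolist()}
        for name, f in frames.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_calibration_frames(path) -> dict:
    raw = json.loads(Path(path).read_text())
    return {
        name: CalibrationFrame(
            si=np.array(v["si"]), ml=np.array(v["ml"]), ap=np.array(v["ap"]), placement=name
        )
        for name, v in raw.items()
    }


def write_angle_table(series_list, path) -> None:
    """Per-trial angle table: time_s, joint, proximal, distal, angle_deg."""
    frames = [
        pd.DataFrame(
            {
                "time_s": s.timestamps,
                "joint": s.joint,
                "proximal": s.proximal,
                "distal": s.distal,
                "angle_deg": s.angles_deg,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_angle_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
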