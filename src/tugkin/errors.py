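"""Bias and RMSE of IMU-derived joint angles against the reference channel.

For every trial x TUG segment x joint x sensor pair, the reference angle
series is linearly interpolated onto the IMU timestamps within the
overlapping time span and two error summaries are computed over each
segment slice:

* bias  = mean(IMU - reference), signed, degrees;
* RMSE  = sqrt(mean((IMU - reference)^2)), degrees.

|bias| <= RMSE always holds (Cauchy-Schwarz) and is asserted on every
record.  Records are collected into a long-format table, one row per
(subject, trial, joint, pair, segment), together with per-cell sample
bookkeeping (n records and distinct subjects), which reflects sensor
dropout exactly: a missing sensor removes all records that involve it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .angles import JointAngleSeries
from .segmentation import SegmentSlice

__all__ = [
    "align_series",
    "bias",
    "rmse",
    "slice_errors",
    "build_error_table",
    "cell_counts",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "subject",
    "trial",
    "joint",
    "proximal",
    "distal",
    "segment",
    "bias_deg",
    "rmse_deg",
    "n_frames",
]


def align_series(
    imu_t: np.ndarray,
    imu_y: np.ndarray,
    ref_t: np.ndarray,
    ref_y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair an IMU series with the reference on the IMU timebase.

    The reference (typically sampled faster, 100/120 Hz vs 40/60 Hz) is
    linearly interpolated onto the IMU timestamps; IMU frames outside the
    overlap of the two spans are dropped.

    Returns
    -------
    (t, imu, ref) : arrays restricted to the overlap.
    """
    imu_t = np.asarray(imu_t, dtype=float)
    imu_y = np.asarray(imu_y, dtype=float)
    ref_t = np.asarray(ref_t, dtype=float)
    ref_y = np.asarray(ref_y, dtype=float)
    lo = max(imu_t[0], ref_t[0])
    hi = min(imu_t[-1], ref_t[-1])
    if not hi >= lo:
        raise ValueError("IMU and reference series do not overlap in time")
    keep = (imu_t >= lo) & (imu_t <= hi)
    t = imu_t[keep]
    return t, imu_y[keep], np.interp(t, ref_t, ref_y)


def bias(imu: np.ndarray, ref: np.ndarray) -> float:
    """Signed mean difference IMU - reference, degrees."""
    imu = np.asarray(imu, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if imu.size < 2:
        raise ValueError("bias requires at least 2 paired samples")
    return float(np.mean(imu - ref))


def rmse(imu: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square difference IMU - reference, degrees."""
    imu = np.asarray(imu, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if imu.size < 2:
        raise ValueError("rmse requires at least 2 paired samples")
    return float(np.sqrt(np.mean((imu - ref) ** 2)))


def slice_errors(
    series: JointAngleSeries,
    ref_t: np.ndarray,
    ref_y: np.ndarray,
    slices: list[SegmentSlice],
    *,
    subject,
    trial,
) -> pd.DataFrame:
    """Per-segment bias/RMSE records for one sensor pair of one trial.

    Segments whose slice covers fewer than two IMU frames are skipped.
    """
    t, imu, ref = align_series(series.timestamps, series.angles_deg, ref_t, ref_y)
    rows = []
    for sl in slices:
        mask = sl.contains(t)
        n = int(mask.sum())
        if n < 2:
            continue
        b = bias(imu[mask], ref[mask])
        r = rmse(imu[mask], ref[mask])
        assert abs(b) <= r + 1e-12, "bias magnitude exceeded RMSE"
        rows.append(
            {
                "subject": subject,
                "trial": trial,
                "joint": series.joint,
                "proximal": series.proximal,
                "distal": series.distal,
                "segment": sl.label,
                "bias_deg": b,
                "rmse_deg": r,
                "n_frames": n,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def build_error_table(trial_inputs) -> pd.DataFrame:
    """Long-format error table over a whole study.

    ``trial_inputs`` yields one tuple per trial:
    ``(subject, trial, series_list, ref_angles, slices)`` where
    ``series_list`` holds the per-pair :class:`JointAngleSeries`,
    ``ref_angles`` is a DataFrame with columns ``time_s`` and one column
    per joint, and ``slices`` the trial's segment slices.  Pairs whose
    sensors were dropped simply do not appear, so per-cell sample counts
    reflect dropout exactly.
    """
    frames = []
    for subject, trial, series_list, ref_angles, slices in trial_inputs:
        ref_t = ref_angles["time_s"].to_numpy()
        for series in series_list:
            frames.append(
                slice_errors(
                    series,
                    ref_t,
                    ref_angles[series.joint].to_numpy(),
                    slices,
                    subject=subject,
                    trial=trial,
                )
            )
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def cell_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Sample bookkeeping per joint x pair x segment cell.

    Returns one row per cell with ``n`` (number of trial-segment records)
    and ``subs`` (distinct contributing subjects), mirroring the "(n = ..
    from .. subs)" annotations of the study tables.
    """
    if records.empty:
        return pd.DataFrame(columns=["joint", "proximal", "distal", "segment", "n", "subs"])
    grp = records.groupby(["joint", "proximal", "distal", "segment"], sort=False)
    out = grp.agg(n=("bias_deg", "size"), subs=("subject", "nunique")).reset_index()
    return out
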