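"""Quaternion-driven segment orientation in a common global frame.

Sensor orientation arrives as unit quaternions (scalar-first ``w,x,y,z``,
Hamilton convention: ``q`` rotates a vector expressed in the sensor frame
into the provider's global frame).  Each calibrated anatomical axis is
rotated frame-by-frame via quaternion conjugation ``q p q^-1``.  Because
the sensors' provider frames are mutually unrelated, all segments are then
mapped into one common global frame using the first captured frame, when
the subject stands upright and all segment axes are assumed parallel: a
direction cosine matrix built from each sensor's frame-one axes sends
those axes onto the canonical basis, and its transpose is applied to every
subsequent frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationFrame

__all__ = [
    "QuaternionStream",
    "SegmentOrientationSeries",
    "quat_multiply",
    "quat_conjugate",
    "rotate_vector",
    "build_dcm",
    "globalize_series",
]

_UNIT_TOL = 1e-6


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product of scalar-first quaternions (broadcasts over leading axes)."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(q1, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(q2, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    """Conjugate (= inverse for unit quaternions), scalar-first."""
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def rotate_vector(q: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``p`` by unit quaternion(s) ``q`` via conjugation.

    The vector is embedded as a pure quaternion ``[0, px, py, pz]`` and the
    rotated vector read back from ``q p q^-1``.  Both arguments broadcast:
    ``q`` may be ``(..., 4)`` and ``p`` ``(..., 3)``.

    Raises
    ------
    ValueError
        If any quaternion norm deviates from 1 by more than 1e-6.
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    norms = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(norms - 1.0) > _UNIT_TOL):
        raise ValueError("non-unit quaternion passed to rotate_vector")
    pq = np.concatenate([np.zeros(p.shape[:-1] + (1,)), p], axis=-1)
    out = quat_multiply(quat_multiply(q, pq), quat_conjugate(q))
    return out[..., 1:]


def build_dcm(a: np.ndarray, b: np.ndarray, c: np.ndarray, *, tol: float = _UNIT_TOL) -> np.ndarray:
    """Direction cosine matrix with columns ``a, b, c``.

    For an orthonormal triad the transpose maps ``a -> [1,0,0]``,
    ``b -> [0,1,0]`` and ``c -> [0,0,1]``, i.e. it expresses vectors in the
    coordinate system spanned by the triad.
    """
    dcm = np.column_stack([a, b, c]).astype(float)
    if np.max(np.abs(dcm.T @ dcm - np.eye(3))) > 10 * tol:
        raise ValueError("build_dcm requires an orthonormal triad")
    return dcm


@dataclass
class QuaternionStream:
    """A sensor's unit-quaternion time series.

    Attributes
    ----------
    timestamps : (n,) seconds, strictly increasing
    q : (n, 4) scalar-first unit quaternions
    placement : sensor placement name
    rate_hz : nominal sampling rate
    """

    timestamps: np.ndarray
    q: np.ndarray
    placement: str
    rate_hz: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[1] != 4:
            raise ValueError("q must have shape (n, 4)")
        if self.timestamps.shape != (self.q.shape[0],):
            raise ValueError("timestamps and q length mismatch")
        if self.timestamps.size == 0:
            raise ValueError("empty quaternion stream")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(np.abs(np.linalg.norm(self.q, axis=1) - 1.0) > _UNIT_TOL):
            raise ValueError("quaternion norms deviate from 1 beyond tolerance")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class SegmentOrientationSeries:
    """Per-frame SI/ML/AP unit vectors of one segment in the common global frame."""

    timestamps: np.ndarray
    si: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    placement: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.si = np.asarray(self.si, dtype=float)
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        n = self.timestamps.shape[0]
        for name, arr in (("si", self.si), ("ml", self.ml), ("ap", self.ap)):
            if arr.shape != (n, 3):
                raise ValueError(f"{name} must have shape ({n}, 3)")

    def __len__(self) -> int:
        return len(self.timestamps)

    def triad(self, i: int) -> np.ndarray:
        """3x3 DCM whose columns are the SI/ML/AP axes at frame ``i``."""
        return np.column_stack([self.si[i], self.ml[i], self.ap[i]])


def globalize_series(frame: CalibrationFrame, stream: QuaternionStream) -> SegmentOrientationSeries:
    """Track a segment's anatomical axes in the common global frame.

    Each calibration axis (expressed in sensor coordinates) is rotated by
    the sensor quaternion at every frame, then the whole series is
    re-expressed in the common global frame anchored at frame one: the DCM
    built from the frame-one rotated axes maps them onto the canonical
    basis, so at frame one SI/ML/AP are exactly ``e1/e2/e3`` for every
    sensor (the parallel-segments assumption of the upright start).
    """
    axes = np.stack([frame.si, frame.ml, frame.ap])          # (3, 3)
    # rotate all 3 axes at all n frames: (n, 3 axes, 3 comps)
    rotated = rotate_vector(stream.q[:, None, :], axes[None, :, :])
    dcm1 = build_dcm(rotated[0, 0], rotated[0, 1], rotated[0, 2])
    common = rotated @ dcm1  # row-vector form of dcm1.T @ v per axis
    return SegmentOrientationSeries(
        timestamps=stream.timestamps,
        si=common[:, 0, :],
        ml=common[:, 1, :],
        ap=common[:, 2, :],
        placement=stream.placement,
    )
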