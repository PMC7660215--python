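"""Two-pose gravity calibration of sensor-to-segment anatomical frames.

Each sensor's anatomical axes are recovered from gravity alone, measured
in two static postures: standing upright and sitting with the legs
outstretched.  Standing gravity fixes the superior-inferior (SI) axis; the
cross product with the seated gravity direction fixes the medial-lateral
(ML) axis; SI x ML gives the anterior-posterior (AP) axis; and a final
cross product AP x SI re-defines ML so the triad is exactly orthonormal.
Both postures must keep the segment in the sagittal plane for the seated
vector to isolate the ML direction.

All sign conventions live in :func:`build_calibration_frame`:

* SI points superiorly (opposite sensed gravity while standing);
* the triad is right-handed with ``SI x ML = AP``;
* the ``seated_tilt`` argument states which way the segment pitches in the
  seated pose (leg segments pitch anteriorly, the trunk posteriorly) and
  orients ML so that AP comes out anterior for every sensor, which makes
  flexion angles positive downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationError",
    "CalibrationFrame",
    "gravity_vector",
    "build_calibration_frame",
]


class CalibrationError(ValueError):
    """Degenerate calibration input (zero acceleration, collinear poses...)."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise CalibrationError("cannot normalize a zero vector")
    return v / n


@dataclass(frozen=True)
class CalibrationFrame:
    """Orthonormal SI/ML/AP anatomical axes expressed in sensor coordinates."""

    si: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    placement: str = ""

    def __post_init__(self) -> None:
        for name in ("si", "ml", "ap"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        triad = np.stack([self.si, self.ml, self.ap])
        if triad.shape != (3, 3):
            raise ValueError("axes must be 3-vectors")
        gram = triad @ triad.T
        if np.max(np.abs(gram - np.eye(3))) > 1e-9:
            raise ValueError("calibration axes must be orthonormal to 1e-9")
        if np.max(np.abs(np.cross(self.si, self.ml) - self.ap)) > 1e-9:
            raise ValueError("calibration triad must be right-handed (SI x ML = AP)")


def gravity_vector(accel_frames: np.ndarray) -> np.ndarray:
    """Unit gravity direction from accelerometer frames of a static pose.

    Parameters
    ----------
    accel_frames : (n, 3) or (3,) array, m/s^2
        Sensed acceleration samples; averaged over all frames before
        normalization.  The sensed vector points along gravity (down).

    Returns
    -------
    (3,) unit vector in sensor coordinates.
    """
    a = np.atleast_2d(np.asarray(accel_frames, dtype=float))
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 1:
        raise ValueError("accel_frames must be an (n, 3) array")
    mean = a.mean(axis=0)
    if np.linalg.norm(mean) == 0.0:
        raise CalibrationError("mean acceleration is zero; cannot infer gravity")
    return _unit(mean)


def build_calibration_frame(
    g_stand: np.ndarray,
    g_sit: np.ndarray,
    *,
    seated_tilt: str = "forward",
    min_separation_deg: float = 5.0,
    placement: str = "",
) -> CalibrationFrame:
    """Anatomical SI/ML/AP frame from the two static gravity directions.

    Parameters
    ----------
    g_stand, g_sit : (3,) vectors in sensor coordinates
        Sensed gravity while standing and while seated; normalized here.
    seated_tilt : {"forward", "backward"}
        Direction the segment pitches in the seated pose, used to orient
        the ML axis so AP is anterior for every sensor.
    min_separation_deg : float
        Minimum angle between the two gravity directions; below this the
        cross product is numerically degenerate.

    Raises
    ------
    CalibrationError
        If the poses are closer than ``min_separation_deg`` apart.
    """
    if seated_tilt not in ("forward", "backward"):
        raise ValueError(f"seated_tilt must be forward/backward, got {seated_tilt!r}")
    si = -gravity_vector(g_stand)
    v_sit = -gravity_vector(g_sit)

    ml_raw = np.cross(si, v_sit)
    if np.linalg.norm(ml_raw) < np.sin(np.deg2rad(min_separation_deg)):
        raise CalibrationError(
            f"standing and seated gravity vectors are within {min_separation_deg} deg "
            f"for sensor {placement or '<unnamed>'}; calibration is degenerate"
        )
    if seated_tilt == "backward":
        ml_raw = -ml_raw
    ml = _unit(ml_raw)
    ap = _unit(np.cross(si, ml))
    ml = np.cross(ap, si)  # exact re-orthogonalization, as in the two-pose procedure
    return CalibrationFrame(si=si, ml=ml, ap=ap, placement=placement)
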