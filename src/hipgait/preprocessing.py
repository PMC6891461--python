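"""Sensor-side preprocessing: IMU bias estimation and joint-angle extraction.

Gyroscope bias is the sample mean of a static recording. Accelerometer bias
is the centre of the least-squares sphere through static samples collected
in several orientations (each noiseless sample lies at distance g from the
bias point, so the samples trace a gravity sphere around it); the fit is the
algebraic Kasa least-squares solution with the radius estimated jointly.

Joint angles come from relative segment orientations: the parent-inverse
composed with the child rotation, decomposed with a configurable intrinsic
Euler sequence (default Z-X-Y: flexion, abduction, internal rotation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "BiasEstimate",
    "JointAngleSeries",
    "estimate_gyro_bias",
    "estimate_accel_bias",
    "joint_angles_from_orientations",
]

_GRAVITY = 9.81


@dataclass
class BiasEstimate:
    gyro_bias: np.ndarray | None  # rad/s
    accel_bias: np.ndarray  # m/s^2, sphere centre
    fitted_radius: float  # m/s^2, should be ~9.81
    fit_residual: float  # RMS distance of samples from the fitted sphere

    def __post_init__(self) -> None:
        if self.fit_residual < 0 or not np.isfinite(self.fit_residual):
            raise ValueError("fit_residual must be finite and non-negative")


@dataclass
class JointAngleSeries:
    """Euler-decomposed relative joint rotation in degrees."""

    flexion: np.ndarray
    abduction: np.ndarray
    rotation: np.ndarray
    sequence: str
    fs: float | None = None
    gimbal_flag: np.ndarray | None = None  # True where middle angle ~ +-90 deg

    def __post_init__(self) -> None:
        for name in ("flexion", "abduction", "rotation"):
            a = getattr(self, name)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite {name} angles")
            if np.any(np.abs(a) >= 180.0 + 1e-9):
                raise ValueError(f"{name} outside (-180, 180) degrees")


def estimate_gyro_bias(static_gyro_samples: np.ndarray) -> np.ndarray:
    """Component-wise mean of a static gyroscope recording (rad/s)."""
    samples = np.atleast_2d(np.asarray(static_gyro_samples, float))
    if samples.size == 0:
        raise ValueError("need at least one gyroscope sample")
    return samples.mean(axis=0)


def estimate_accel_bias(static_accel_samples: np.ndarray,
                        gravity: float = _GRAVITY) -> BiasEstimate:
    """Sphere-fit accelerometer bias from multi-orientation static samples.

    Solves the linear (Kasa) least squares ``2 x.c + (r^2 - |c|^2) = |x|^2``
    for the sphere centre ``c`` (the bias) and radius ``r``. The sample cloud
    must span at least four non-coplanar orientations; a degenerate
    (coplanar/collinear) cloud leaves the centre unidentifiable and raises.
    ``gravity`` is only used to report how far the fitted radius is from the
    expected local value — it does not constrain the fit.
    """
    x = np.atleast_2d(np.asarray(static_accel_samples, float))
    if x.shape[0] < 4 or x.shape[1] != 3:
        raise ValueError("need >=4 samples of shape (n, 3)")
    A = np.column_stack([2.0 * x, np.ones(len(x))])
    b = np.einsum("ij,ij->i", x, x)
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4 or sv[-1] / sv[0] < 1e-10:
        raise ValueError(
            "degenerate sample geometry: sphere centre unidentifiable "
            "(samples coplanar or collinear)")
    center = sol[:3]
    r_sq = sol[3] + center @ center
    if r_sq <= 0:
        raise ValueError("sphere fit collapsed (non-positive radius)")
    radius = float(np.sqrt(r_sq))
    dist = np.linalg.norm(x - center, axis=1)
    residual = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return BiasEstimate(gyro_bias=None, accel_bias=center,
                        fitted_radius=radius, fit_residual=residual)


def _as_rotation(series, tol: float) -> Rotation:
    if isinstance(series, Rotation):
        if series.single:
            return Rotation.from_quat(series.as_quat()[None, :])
        return series
    q = np.atleast_2d(np.asarray(series, float))
    if q.shape[1] != 4:
        raise ValueError("orientation series must be (n, 4) quaternions")
    norms = np.linalg.norm(q, axis=1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError("non-unit quaternions beyond tolerance")
    # scalar-first (w, x, y, z) at the interface; scipy wants scalar-last
    return Rotation.from_quat(np.column_stack([q[:, 1:], q[:, :1]]))


def joint_angles_from_orientations(parent, child, sequence: str = "ZXY",
                                   fs: float | None = None,
                                   unit_tol: float = 1e-6,
                                   gimbal_margin_deg: float = 1.0
                                   ) -> JointAngleSeries:
    """Decompose the parent-to-child relative rotation into joint angles.

    ``parent`` / ``child`` are equal-length series of unit quaternions
    (scalar-first) or ``scipy`` Rotations mapping segment to world frames.
    The relative rotation ``parent^-1 * child`` is decomposed with the
    intrinsic Euler ``sequence``; the three returned angle series follow the
    sequence order (default flexion about Z, abduction about X, rotation
    about Y). Samples whose middle angle lies within ``gimbal_margin_deg``
    of +-90 degrees are flagged, not rejected.
    """
    rp = _as_rotation(parent, unit_tol)
    rc = _as_rotation(child, unit_tol)
    if len(rp) != len(rc):
        raise ValueError("parent and child series must have equal length")
    rel = rp.inv() * rc
    angles = rel.as_euler(sequence, degrees=True)
    angles = np.atleast_2d(angles)
    gimbal = np.abs(np.abs(angles[:, 1]) - 90.0) < gimbal_margin_deg
    return JointAngleSeries(
        flexion=angles[:, 0], abduction=angles[:, 1], rotation=angles[:, 2],
        sequence=sequence, fs=fs, gimbal_flag=gimbal)
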