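"""Sensor calibration surrogates and strap-down orientation integration.

The cited joint-drift-correction literature is an external dependency of
the original processing chain; here its role is played by a gated
complementary filter that slowly steers the integrated inclination toward
the low-frequency accelerometer gravity direction, leaving any residual
drift to the smoother's three Euler drift states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import (
    FRAME_INERTIAL,
    GRAVITY,
    InvalidInputError,
    NotStaticError,
    OrientationTimeline,
    TimeSeries3D,
    UP,
    gravity_vector,
    minimal_rotation,
)


@dataclass
class CalibrationParams:
    """Per-sensor calibration state.

    Offsets/sensitivities model the affine accelerometer correction, the
    gyro bias is removed before integration, and the sensor-to-segment
    rotation comes from the functional calibration posture.
    """

    accel_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_sensitivity: np.ndarray = field(default_factory=lambda: np.ones(3))
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mag_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    mag_affine: np.ndarray = field(default_factory=lambda: np.eye(3))
    sensor_to_segment: Rotation = field(default_factory=Rotation.identity)

    def __post_init__(self):
        if np.any(np.asarray(self.accel_sensitivity) <= 0):
            raise InvalidInputError("sensitivities must be positive")
        if abs(np.linalg.det(np.asarray(self.mag_affine))) < 1e-12:
            raise InvalidInputError("magnetometer affine matrix must be invertible")

    def apply_accel(self, acc: TimeSeries3D) -> TimeSeries3D:
        vals = (acc.values - self.accel_offset) / self.accel_sensitivity
        return acc.with_values(vals)

    def apply_gyro(self, gyro: TimeSeries3D) -> TimeSeries3D:
        return gyro.with_values(gyro.values - self.gyro_bias)


def estimate_gyro_bias(static_window: TimeSeries3D,
                       std_threshold: float = 0.05) -> np.ndarray:
    """Per-axis mean angular velocity over a static window.

    Raises :class:`NotStaticError` when the window shows motion (per-axis
    standard deviation above ``std_threshold`` rad/s) or is shorter than
    0.5 s.
    """
    if static_window.t[-1] - static_window.t[0] < 0.5 - 1e-9:
        raise InvalidInputError("static window must be at least 0.5 s")
    std = static_window.values.std(axis=0)
    if np.any(std > std_threshold):
        raise NotStaticError(f"gyro std {std} exceeds {std_threshold} rad/s")
    return static_window.values.mean(axis=0)


def _rolling_power(values: np.ndarray, n_win: int) -> np.ndarray:
    kernel = np.ones(n_win) / n_win
    power = np.zeros(values.shape[0])
    for k in range(values.shape[1]):
        x = values[:, k]
        mean = np.convolve(x, kernel, mode="same")
        power += np.convolve(x * x, kernel, mode="same") - mean**2
    return power


def detect_static_windows(gyro: TimeSeries3D, acc: TimeSeries3D | None = None,
                          window: float = 0.5,
                          std_threshold: float = 0.03,
                          acc_std_threshold: float = 0.1,
                          min_duration: float = 1.0) -> list[tuple[float, float]]:
    """Static intervals from the rolling dispersion of gyro (and accel).

    Returns maximal intervals (seconds) where the angular velocity — and,
    when an accelerometer signal is given, the specific force — stays
    quiet; a quiet gyro alone does not discriminate a straight-line speed
    ramp from standing still, so the pipeline always passes both.  The
    start and finish postures of a run show up as the first and last
    interval.
    """
    n_win = max(2, int(round(window * gyro.rate)))
    quiet = _rolling_power(gyro.values, n_win) < std_threshold**2
    if acc is not None:
        quiet &= _rolling_power(acc.values, n_win) < acc_std_threshold**2
    intervals = []
    start = None
    for i, q in enumerate(quiet):
        if q and start is None:
            start = i
        elif not q and start is not None:
            intervals.append((start, i - 1))
            start = None
    if start is not None:
        intervals.append((start, len(quiet) - 1))
    out = []
    for i0, i1 in intervals:
        t0, t1 = gyro.t[i0], gyro.t[i1]
        if t1 - t0 >= min_duration:
            out.append((float(t0), float(t1)))
    return out


def functional_alignment(static_acc: TimeSeries3D,
                         segment_axis: np.ndarray = UP,
                         std_threshold: float = 0.5) -> CalibrationParams:
    """Sensor-to-segment rotation from the static upright posture.

    In the static posture the specific force points along the segment's
    longitudinal (vertical) axis; the smallest rotation mapping the mean
    measured direction onto ``segment_axis`` aligns the sensor without
    introducing any azimuth twist, consistent with the convention that the
    global azimuth is zero at the start posture.
    """
    std = static_acc.values.std(axis=0)
    if np.any(std > std_threshold):
        raise NotStaticError(f"accelerometer std {std} exceeds {std_threshold}")
    mean = static_acc.values.mean(axis=0)
    if np.linalg.norm(mean) < 1e-6:
        raise InvalidInputError("mean specific force is zero")
    return CalibrationParams(sensor_to_segment=minimal_rotation(mean, segment_axis))


def initial_orientation_from_accel(static_acc: TimeSeries3D) -> Rotation:
    """Initial segment-to-global rotation: inclination from gravity, azimuth 0."""
    mean = static_acc.values.mean(axis=0)
    if np.linalg.norm(mean) < 1e-6:
        raise InvalidInputError("mean specific force is zero")
    return minimal_rotation(mean, UP)


def _quat_mult(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]])
    axis = v / angle
    half = 0.5 * angle
    s = np.sin(half)
    return np.array([np.cos(half), s * axis[0], s * axis[1], s * axis[2]])


def _rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    qv = np.array([x, y, z])
    t = 2.0 * np.cross(qv, v)
    return v + w * t + np.cross(qv, t)


def strapdown_orientation(gyro: TimeSeries3D, initial: Rotation,
                          acc: TimeSeries3D | None = None,
                          time_constant: float = 10.0,
                          accel_gate: float = 0.15,
                          gravity: float = GRAVITY) -> OrientationTimeline:
    """Quaternion integration of the angular velocity at the sensor rate.

    Per-sample first-order exponential map (angular velocity assumed
    constant over each step).  When ``acc`` is supplied, a complementary
    inclination correction with time constant ``time_constant`` steers the
    integrated gravity direction toward the measured specific-force
    direction, but only while the specific-force magnitude is within
    ``accel_gate`` (fractional) of gravity — i.e. quasi-static samples.
    """
    if acc is not None and len(acc) != len(gyro):
        raise InvalidInputError("acc and gyro must be aligned")
    dt = gyro.dt
    n = len(gyro)
    omegas = gyro.values
    quats = np.empty((n, 4))
    # scipy quaternions are (x, y, z, w); internal convention is (w, x, y, z)
    qs = initial.as_quat()
    q = np.array([qs[3], qs[0], qs[1], qs[2]])
    quats[0] = q
    gain = dt / time_constant
    use_acc = acc is not None
    if use_acc:
        f = acc.values
        f_norm = np.linalg.norm(f, axis=1)
        gated = np.abs(f_norm - gravity) < accel_gate * gravity
    for i in range(1, n):
        dq = _quat_from_rotvec(omegas[i - 1] * dt)
        q = _quat_mult(q, dq)
        q /= np.linalg.norm(q)
        if use_acc and gated[i]:
            up_meas = _rotate(q, f[i] / f_norm[i])
            corr = np.cross(up_meas, UP) * gain
            q = _quat_mult(_quat_from_rotvec(corr), q)
            q /= np.linalg.norm(q)
        quats[i] = q
    rot = Rotation.from_quat(np.column_stack([quats[:, 1], quats[:, 2],
                                              quats[:, 3], quats[:, 0]]))
    return OrientationTimeline(gyro.t.copy(), rot, FRAME_INERTIAL)


def global_linear_acceleration(acc: TimeSeries3D, orient: OrientationTimeline,
                               gravity: float = GRAVITY) -> TimeSeries3D:
    """Gravity-free linear acceleration in the global frame.

    ``a(t) = R(t) f(t) + g_vec`` with ``f`` the measured specific force and
    ``g_vec = (0, -g, 0)``; a stationary, correctly oriented sensor maps to
    zero, a free-falling one (f = 0) to the gravity vector.
    """
    if len(acc) != len(orient):
        raise InvalidInputError("acc and orientation timelines must be aligned")
    a_global = orient.rotations.apply(acc.values) + gravity_vector(gravity)
    return TimeSeries3D(acc.t.copy(), a_global, FRAME_INERTIAL)
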