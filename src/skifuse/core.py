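"""Shared types, frame conventions and generic signal operators.

Frame conventions
-----------------
All global frames are right-handed with the Y axis vertical, pointing *up*:
gravity acts along -Y.  Three global frames appear in the pipeline:

``J``
    inertial global frame: X forward with respect to the athlete's still
    posture at the start, Y up, Z = X x Y (to the athlete's right); origin
    at the sacrum position at the start.
``G``
    Earth (course survey) frame in which gate positions are expressed.
    Differs from ``J`` only by an azimuth rotation about Y and a
    translation, both recovered by anchor-point matching.
``S``
    local skiing frame, re-built at every sample from the reference
    velocity: x along the velocity, z = x x up, y = z x x.

Orientations are carried by :class:`scipy.spatial.transform.Rotation`;
a rotation ``R`` attached to a segment maps segment-frame coordinates to
global-frame coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, lfilter
from scipy.spatial.transform import Rotation

GRAVITY = 9.81  # m/s^2, configurable through the functions that use it

FRAME_SENSOR = "sensor"
FRAME_INERTIAL = "J"
FRAME_EARTH = "G"
FRAME_SKIING = "S"

UP = np.array([0.0, 1.0, 0.0])


def gravity_vector(gravity: float = GRAVITY) -> np.ndarray:
    """Gravity acceleration vector (points down, along -Y)."""
    return np.array([0.0, -gravity, 0.0])


class InvalidParameterError(ValueError):
    """A parameter violates an operation's precondition."""


class InvalidInputError(ValueError):
    """Input data violate an operation's precondition."""


class NotStaticError(InvalidInputError):
    """A window assumed static contains motion."""


class DegenerateGeometryError(InvalidInputError):
    """Geometry is too degenerate to solve (collinear points, ...)."""


class AmbiguousAzimuthError(DegenerateGeometryError):
    """Point cloud too isotropic for a principal-direction azimuth."""


class MatchingFailedError(RuntimeError):
    """Anchor point matching produced no surviving pairs."""


class PipelineError(RuntimeError):
    """The fusion pipeline could not complete."""


@dataclass
class TimeSeries3D:
    """Uniformly sampled 3-vector signal.

    Parameters
    ----------
    t : (n,) array of timestamps in seconds, uniform step.
    values : (n, 3) array of 3-vectors.
    frame_id : name of the frame the vectors are expressed in.
    """

    t: np.ndarray
    values: np.ndarray
    frame_id: str

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.ndim != 1 or self.values.shape != (self.t.size, 3):
            raise InvalidInputError(
                f"shape mismatch: t {self.t.shape}, values {self.values.shape}"
            )
        if not self.frame_id:
            raise InvalidInputError("frame_id must be set")
        if self.t.size >= 2:
            steps = np.diff(self.t)
            if steps.min() <= 0:
                raise InvalidInputError("timestamps must increase monotonically")
            if np.ptp(steps) > 1e-9:
                raise InvalidInputError("sampling step must be uniform to 1e-9 s")

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise InvalidInputError("need >= 2 samples for a sampling step")
        return float(self.t[1] - self.t[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def with_values(self, values: np.ndarray, frame_id: str | None = None) -> "TimeSeries3D":
        return TimeSeries3D(self.t.copy(), values, frame_id or self.frame_id)

    def slice_time(self, t0: float, t1: float) -> "TimeSeries3D":
        mask = (self.t >= t0) & (self.t <= t1)
        return TimeSeries3D(self.t[mask], self.values[mask], self.frame_id)

    def interp(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the signal at arbitrary times."""
        t = np.asarray(t, dtype=float)
        out = np.stack([np.interp(t, self.t, self.values[:, k]) for k in range(3)], axis=-1)
        return out

    def norm(self) -> np.ndarray:
        return np.linalg.norm(self.values, axis=1)


@dataclass
class FrameConvention:
    """Global-frame definition used throughout the pipeline."""

    gravity: float = GRAVITY
    # axes stored as rows for documentation purposes; the frames are
    # axis-aligned by construction so this is rarely needed numerically
    x_forward: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    y_up: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    @property
    def gravity_vector(self) -> np.ndarray:
        return -self.gravity * self.y_up


@dataclass
class OrientationTimeline:
    """Per-sample rotation from a segment frame to a global frame."""

    t: np.ndarray
    rotations: Rotation
    frame_id: str = FRAME_INERTIAL

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if len(self.rotations) != self.t.size:
            raise InvalidInputError("t and rotations length mismatch")

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def matrices(self) -> np.ndarray:
        return self.rotations.as_matrix()


# ---------------------------------------------------------------------------
# rotation helpers


def rotation_about_y(angle: float) -> Rotation:
    """Rotation by ``angle`` about the vertical (Y) axis."""
    return Rotation.from_rotvec([0.0, angle, 0.0])


def horizontal_angle(v: np.ndarray) -> float:
    """Signed azimuth of the horizontal projection of ``v``.

    Defined so that ``horizontal_angle(rotation_about_y(a).apply(v)) ==
    horizontal_angle(v) + a`` (a rotation about +Y takes +X toward -Z).
    """
    v = np.asarray(v, dtype=float)
    return float(np.arctan2(-v[2], v[0]))


def minimal_rotation(v_from: np.ndarray, v_to: np.ndarray) -> Rotation:
    """Smallest rotation mapping direction ``v_from`` onto ``v_to``."""
    a = np.asarray(v_from, float)
    b = np.asarray(v_to, float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return Rotation.identity()
        # antiparallel: pick any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp)
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(axis / s * angle)


def skew(v: np.ndarray) -> np.ndarray:
    """Cross-product matrix: skew(v) @ u == v x u."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def local_skiing_frame(v_ref: np.ndarray, gravity_dir: np.ndarray,
                       min_angle_deg: float = 1.0) -> Rotation:
    """Local skiing frame from a reference velocity and the gravity vector.

    x is along ``v_ref``; z = x x up (up being the direction opposite to
    gravity); y = z x x.  Returns the rotation whose matrix columns are the
    frame axes expressed in the parent frame, so ``R.T @ d`` expresses a
    parent-frame vector ``d`` in skiing-frame coordinates.
    """
    v = np.asarray(v_ref, dtype=float)
    g = np.asarray(gravity_dir, dtype=float)
    nv = np.linalg.norm(v)
    ng = np.linalg.norm(g)
    if nv == 0 or ng == 0:
        raise InvalidParameterError("v_ref and gravity_dir must be non-zero")
    x = v / nv
    up = -g / ng
    cross = np.cross(x, up)
    s = np.linalg.norm(cross)
    if s < np.sin(np.deg2rad(min_angle_deg)):
        raise DegenerateGeometryError("velocity nearly parallel to gravity")
    z = cross / s
    y = np.cross(z, x)
    return Rotation.from_matrix(np.column_stack([x, y, z]))


def local_skiing_frames(v_ref: np.ndarray, gravity_dir: np.ndarray) -> np.ndarray:
    """Vectorised skiing frames for an (n, 3) velocity array.

    Returns an (n, 3, 3) array of rotation matrices (columns = axes).
    Samples where the velocity is degenerate reuse the previous valid
    frame (or identity at the very start) rather than raising, because
    validation runs include static windows with zero velocity.
    """
    v = np.asarray(v_ref, dtype=float)
    g = np.asarray(gravity_dir, dtype=float)
    up = -g / np.linalg.norm(g)
    n = v.shape[0]
    x = np.zeros_like(v)
    nv = np.linalg.norm(v, axis=1)
    ok = nv > 1e-9
    x[ok] = v[ok] / nv[ok, None]
    z = np.cross(x, np.broadcast_to(up, v.shape))
    nz = np.linalg.norm(z, axis=1)
    ok &= nz > np.sin(np.deg2rad(1.0))
    z[ok] = z[ok] / np.linalg.norm(z[ok], axis=1)[:, None]
    y = np.cross(z, x)
    mats = np.empty((n, 3, 3))
    mats[:, :, 0] = x
    mats[:, :, 1] = y
    mats[:, :, 2] = z
    last = np.eye(3)
    for i in range(n):
        if ok[i]:
            last = mats[i]
        else:
            mats[i] = last
    return mats


# ---------------------------------------------------------------------------
# signal operators


def butterworth_lowpass(x: TimeSeries3D, order: int, cutoff: float,
                        zero_phase: bool = True) -> TimeSeries3D:
    """Low-pass Butterworth filter, forward-backward by default.

    The zero-phase (filtfilt) variant squares the magnitude response but
    leaves no phase lag, which matters when comparing trajectories sample
    by sample.  ``zero_phase=False`` gives the causal single pass.
    """
    nyquist = x.rate / 2.0
    if not 0 < cutoff < nyquist:
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyquist} Hz)")
    if len(x) <= 3 * order:
        raise InvalidInputError("signal too short for the requested filter order")
    b, a = butter(order, cutoff / nyquist)
    if zero_phase:
        out = filtfilt(b, a, x.values, axis=0)
    else:
        out = lfilter(b, a, x.values, axis=0)
    return x.with_values(out)


def three_point_derivative(p: TimeSeries3D) -> TimeSeries3D:
    """Central-difference derivative; one-sided differences at the ends."""
    if len(p) < 3:
        raise InvalidInputError("need at least 3 samples")
    v = np.gradient(p.values, p.dt, axis=0, edge_order=1)
    return p.with_values(v)


def resample_uniform(x: TimeSeries3D, rate: float) -> TimeSeries3D:
    """Linear-interpolation resampling onto a uniform grid at ``rate`` Hz."""
    if rate <= 0:
        raise InvalidParameterError("rate must be positive")
    if len(x) == 0:
        raise InvalidInputError("empty input")
    n = int(np.floor((x.t[-1] - x.t[0]) * rate)) + 1
    t_new = x.t[0] + np.arange(n) / rate
    vals = np.stack([np.interp(t_new, x.t, x.values[:, k]) for k in range(3)], axis=1)
    return TimeSeries3D(t_new, vals, x.frame_id)


def cumulative_trapezoid_integral(x: TimeSeries3D, initial: np.ndarray | None = None,
                                  frame_id: str | None = None) -> TimeSeries3D:
    """Trapezoid-rule running integral, the inverse of trapezoid differencing."""
    init = np.zeros(3) if initial is None else np.asarray(initial, float)
    inc = 0.5 * (x.values[1:] + x.values[:-1]) * x.dt
    out = np.empty_like(x.values)
    out[0] = init
    out[1:] = init + np.cumsum(inc, axis=0)
    return TimeSeries3D(x.t.copy(), out, frame_id or x.frame_id)
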