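"""Synthetic giant-slalom runs with ground truth and noisy sensor signals.

The simulator stands in for a field campaign: it lays out a ~30-gate
course on an inclined plane, threads a smooth center-of-mass line through
the gate corridor, derives a plausible whole-body posture (lean into the
turn, fixed hip/knee flexion), and synthesises the body-worn sensor
signals — 500 Hz accelerometer/gyroscope per segment and a 125 Hz
magnetometer at the sacrum whose field norm rises as a magnetic dipole
(1/r^3) near each buried gate magnet.

Ground-truth sacrum kinematics are defined *discretely*: the analytic
acceleration samples are integrated with the trapezoid rule, so that
noise-free re-integration of the synthesised signals reproduces the
ground-truth trajectory to numerical precision.  All randomness flows
from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from . import body_model as bm
from .anchors import AnchorSet, course_turn_directions
from .core import (
    FRAME_EARTH,
    FRAME_SENSOR,
    GRAVITY,
    InvalidParameterError,
    OrientationTimeline,
    TimeSeries3D,
    gravity_vector,
    horizontal_angle,
)

#: forward dipole field model constants: ||B|| = 1 + c / max(r, r_min)^3.
#: c is chosen so that inverting the piecewise-linear intensity-to-distance
#: calibration recovers the true distance to within ~0.06 m for
#: r in [0.2, 0.6] m; beyond ~0.6 m the calibration saturates by design.
DIPOLE_CONSTANT = 0.03
DIPOLE_MIN_DISTANCE = 0.1

#: arbitrary but fixed ambient field direction (unit norm far from magnets)
EARTH_FIELD_DIR = np.array([0.43, -0.76, 0.49]) / np.linalg.norm([0.43, -0.76, 0.49])

SENSOR_RATE = 500.0
MAG_DECIMATION = 4  # 500 Hz -> 125 Hz


@dataclass
class CourseSpec:
    """Giant-slalom course geometry."""

    n_gates: int = 30
    gate_spacing: tuple[float, float] = (21.8, 27.8)  # 3D, meters
    total_length: float = 700.0
    vertical_drop: float = 150.0
    lateral_amplitude: float = 3.0  # gate offset left/right of the center line

    def __post_init__(self):
        if self.n_gates < 2:
            raise InvalidParameterError("need at least two gates")
        lo, hi = self.gate_spacing
        if not 0 < lo <= hi:
            raise InvalidParameterError("invalid spacing range")
        if 2 * self.lateral_amplitude >= lo:
            raise InvalidParameterError("lateral amplitude too large for spacing")
        if self.vertical_drop >= self.total_length:
            raise InvalidParameterError("vertical drop exceeds course length")
        mean_span = 0.5 * (lo + hi) * (self.n_gates - 1)
        if abs(mean_span - self.total_length) > 0.2 * self.total_length:
            raise InvalidParameterError(
                f"gate spacing x count ({mean_span:.0f} m) inconsistent with "
                f"total length {self.total_length:.0f} m by more than 20%")


@dataclass
class SensorNoiseModel:
    """Additive sensor noise and slowly varying bias magnitudes."""

    accel_sigma: float = 0.015  # m/s^2 white noise per 500 Hz sample
    gyro_sigma: float = 0.003   # rad/s white noise per sample
    gyro_bias: float = 0.01     # rad/s constant bias (per-axis sigma)
    mag_sigma: float = 0.005    # normalised field units per 125 Hz sample
    seed: int = 0

    def __post_init__(self):
        for name in ("accel_sigma", "gyro_sigma", "gyro_bias", "mag_sigma"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls, seed: int = 0) -> "SensorNoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, seed)


@dataclass
class GroundTruth:
    """Reference kinematics of one simulated run (Earth frame G)."""

    sacrum: TimeSeries3D
    sacrum_velocity: TimeSeries3D
    sacrum_acceleration: TimeSeries3D
    com: TimeSeries3D
    com_velocity: TimeSeries3D
    orientations: dict[str, OrientationTimeline]
    gates: AnchorSet
    gate_directions: list[str]
    gate_crossing_times: np.ndarray
    gate_crossing_distances: np.ndarray
    static_windows: list[tuple[float, float]]
    body: bm.BodySegmentModel
    true_azimuth: float
    meta: dict = field(default_factory=dict)

    @property
    def t(self) -> np.ndarray:
        return self.sacrum.t


@dataclass
class SensorSet:
    """Synthesised sensor observations for one run."""

    accel: dict[str, TimeSeries3D]
    gyro: dict[str, TimeSeries3D]
    mag: TimeSeries3D
    rate: float = SENSOR_RATE


def generate_course(spec: CourseSpec, seed: int = 0) -> AnchorSet:
    """Surveyed gate positions on an inclined plane, Earth frame.

    Gates alternate left/right of a straight center line; consecutive 3D
    gate distances are drawn inside the configured range.  The whole course is
    rotated by a seeded azimuth and translated, so the survey frame G does
    not coincide with the athlete's inertial frame J.
    """
    rng = np.random.default_rng(seed)
    lo, hi = spec.gate_spacing
    amp = spec.lateral_amplitude
    margin = 0.02 * (hi - lo)
    spacings = rng.uniform(lo + margin, hi - margin, spec.n_gates - 1)

    slope = np.arcsin(spec.vertical_drop / spec.total_length)
    along = np.array([np.cos(slope), -np.sin(slope), 0.0])  # downhill
    lateral = np.array([0.0, 0.0, 1.0])

    signs = np.empty(spec.n_gates)
    signs[::2] = 1.0
    signs[1::2] = -1.0
    lat = amp * signs
    dlat = np.abs(np.diff(lat))
    dalong = np.sqrt(np.maximum(spacings**2 - dlat**2, 1.0))
    s = np.concatenate([[0.0], np.cumsum(dalong)])
    pts = s[:, None] * along + lat[:, None] * lateral

    azimuth = rng.uniform(-0.9 * np.pi, 0.9 * np.pi)
    rot = Rotation.from_rotvec([0.0, azimuth, 0.0])
    origin = np.array([rng.uniform(-100, 100), rng.uniform(0, 50),
                       rng.uniform(-100, 100)])
    return AnchorSet(rot.apply(pts) + origin)


def _smoothstep_integral(x: np.ndarray) -> np.ndarray:
    """Running integral of the cubic smoothstep on [0, 1] (value 1/2 at 1)."""
    xc = np.clip(x, 0.0, 1.0)
    base = xc**3 - 0.5 * xc**4
    return base + np.where(x > 1.0, x - 1.0, 0.0)


def _second_derivative(values: np.ndarray, dt: float) -> np.ndarray:
    """Fourth-order central second derivative; ends padded (static there)."""
    out = np.zeros_like(values)
    c = np.array([-1.0, 16.0, -30.0, 16.0, -1.0]) / (12.0 * dt * dt)
    for k, ck in zip(range(-2, 3), c):
        out[2:-2] += ck * values[2 + k:values.shape[0] - 2 + k]
    return out


def _fit_plane_normal(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    n = vt[2]
    return n if n[1] > 0 else -n


def generate_trajectory(course: AnchorSet, mean_speed: float = 20.0,
                        rate: float = SENSOR_RATE, seed: int = 0,
                        pass_distance: float = 0.3,
                        static_duration: float = 2.5,
                        ramp_time: float = 3.0,
                        hip_flexion: float = np.deg2rad(50.0),
                        knee_flexion: float = np.deg2rad(70.0),
                        trunk_pitch: float = np.deg2rad(-20.0),
                        max_lean: float = np.deg2rad(72.0),
                        angulation_gain: float = 0.3,
                        model: bm.BodySegmentModel | None = None,
                        max_pass_distance: float = 0.7) -> GroundTruth:
    """Ground-truth run through a course.

    The sacrum (LJC) line is a C2 spline through waypoints offset
    ``pass_distance`` laterally outward of each gate, elevated above the
    snow plane by the leg extent foreshortened with the lean angle; the
    lean follows the quasi-static balance angle atan(a_lat / g).  Static
    postures of ``static_duration`` seconds precede and follow the run.
    """
    if mean_speed <= 0:
        raise InvalidParameterError("mean_speed must be positive")
    model = model or bm.BodySegmentModel()
    dt = 1.0 / rate
    gates = course.positions
    dirs = course_turn_directions(course)
    normal = _fit_plane_normal(gates)

    # --- waypoints: gate + pass_distance outward of the turn
    tangents = np.gradient(gates, axis=0)
    tangents[:, 1] = 0.0
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    right = np.cross(tangents, [0.0, 1.0, 0.0])
    right /= np.linalg.norm(right, axis=1)[:, None]
    outward = np.where(np.array([d == "left" for d in dirs])[:, None], right, -right)
    waypoints = gates + pass_distance * outward
    run_in = gates[0] - 30.0 * (tangents[0] - np.dot(tangents[0], normal) * normal)
    run_out = gates[-1] + 30.0 * (tangents[-1] - np.dot(tangents[-1], normal) * normal)
    pts = np.vstack([run_in, waypoints, run_out])

    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    spline = CubicSpline(chord, pts, bc_type="natural")

    # chord -> arc length lookup
    u_fine = np.linspace(0.0, chord[-1], int(chord[-1] * 8))
    dp = spline(u_fine, 1)
    speed_u = np.linalg.norm(dp, axis=1)
    s_fine = np.concatenate([[0.0], np.cumsum(0.5 * (speed_u[1:] + speed_u[:-1])
                                              * np.diff(u_fine))])
    total_arc = s_fine[-1]

    # --- speed profile: smoothstep ramps, constant cruise
    v_c = mean_speed
    if total_arc <= v_c * ramp_time:
        raise InvalidParameterError("course too short for the speed profile")
    t_cruise = (total_arc - v_c * ramp_time) / v_c
    t_move = 2 * ramp_time + t_cruise
    t_total = 2 * static_duration + t_move
    n = int(np.round(t_total * rate)) + 1
    t = np.arange(n) * dt

    tm = np.clip(t - static_duration, 0.0, t_move)
    s = v_c * ramp_time * _smoothstep_integral(tm / ramp_time)
    tail = np.clip(tm - (ramp_time + t_cruise), 0.0, ramp_time)
    s -= v_c * ramp_time * _smoothstep_integral(tail / ramp_time)
    s = np.clip(s, 0.0, total_arc)

    u = np.interp(s, s_fine, u_fine)
    path = spline(u)
    tangent3 = spline(u, 1)
    tangent3 /= np.linalg.norm(tangent3, axis=1)[:, None]

    # --- lean from the quasi-static balance angle
    v_path = np.gradient(path, dt, axis=0)
    a_path = np.gradient(v_path, dt, axis=0)
    right3 = np.cross(tangent3, [0.0, 1.0, 0.0])
    right3 /= np.linalg.norm(right3, axis=1)[:, None]
    a_lat = np.einsum("ij,ij->i", a_path, right3)
    lean = np.arctan2(a_lat, GRAVITY)
    b, a = butter(2, 2.0 / (rate / 2.0))
    lean = np.clip(filtfilt(b, a, lean), -max_lean, max_lean)

    # --- body orientation triad: x forward on plane, y leaned off the normal
    extent = bm.leg_vertical_extent(model, hip_flexion, knee_flexion)
    x_b = tangent3 - np.einsum("ij,j->i", tangent3, normal)[:, None] * normal
    x_b /= np.linalg.norm(x_b, axis=1)[:, None]
    right_p = np.cross(x_b, normal)  # on-plane right
    y_b = np.cos(lean)[:, None] * normal + np.sin(lean)[:, None] * right_p
    z_b = np.cross(x_b, y_b)
    mats = np.stack([x_b, y_b, z_b], axis=2)
    r_body = Rotation.from_matrix(mats)

    # --- discrete-consistent sacrum kinematics
    ljc_raw = path + extent * np.cos(lean)[:, None] * normal
    acc = _second_derivative(ljc_raw, dt)
    vel = np.zeros_like(acc)
    vel[1:] = np.cumsum(0.5 * (acc[1:] + acc[:-1]) * dt, axis=0)
    pos = np.empty_like(vel)
    pos[0] = ljc_raw[0]
    pos[1:] = ljc_raw[0] + np.cumsum(0.5 * (vel[1:] + vel[:-1]) * dt, axis=0)

    sacrum = TimeSeries3D(t, pos, FRAME_EARTH)
    sacrum_v = TimeSeries3D(t, vel, FRAME_EARTH)
    sacrum_a = TimeSeries3D(t, acc, FRAME_EARTH)

    # --- segment orientations: fixed hip/trunk angles shared across the
    # body, plus a lean-proportional knee angulation (the inside leg flexes
    # more), which is what makes the equal-ankle-distance turn-switch
    # criterion observable
    rz = lambda ang: Rotation.from_rotvec([0.0, 0.0, ang])
    rz_t = lambda angles: Rotation.from_rotvec(
        np.column_stack([np.zeros_like(angles), np.zeros_like(angles), angles]))
    knee_r = knee_flexion + angulation_gain * lean   # lean > 0 = right lean
    knee_l = knee_flexion - angulation_gain * lean
    orientations = {
        "pelvis": r_body,
        "trunk": r_body * rz(trunk_pitch),
        "head": r_body * rz(0.5 * trunk_pitch),
        "thigh_l": r_body * rz(hip_flexion),
        "thigh_r": r_body * rz(hip_flexion),
        "shank_l": r_body * rz_t(hip_flexion - knee_l),
        "shank_r": r_body * rz_t(hip_flexion - knee_r),
    }
    orientations = {k: OrientationTimeline(t, v, FRAME_EARTH)
                    for k, v in orientations.items()}

    rel = bm.relative_com(orientations, model)
    com = TimeSeries3D(t, pos + rel.values, FRAME_EARTH)
    com_v = TimeSeries3D(t, vel + np.gradient(rel.values, dt, axis=0), FRAME_EARTH)

    # --- gate crossings: closest approach of the sacrum line
    cross_t = np.empty(len(gates))
    cross_d = np.empty(len(gates))
    lateral_d = np.empty(len(gates))
    for i, g in enumerate(gates):
        d2 = np.sum((pos - g)**2, axis=1)
        j = int(np.argmin(d2))
        cross_t[i] = t[j]
        cross_d[i] = np.sqrt(d2[j])
        horiz = (pos - g)[:, [0, 2]]
        lateral_d[i] = np.sqrt(np.min(np.sum(horiz**2, axis=1)))
    if np.any(lateral_d > max_pass_distance):
        raise InvalidParameterError(
            f"trajectory misses a gate laterally by more than {max_pass_distance} m")

    static_windows = [(0.0, static_duration), (float(t[-1]) - static_duration, float(t[-1]))]
    true_azimuth = horizontal_angle(x_b[0])

    return GroundTruth(
        sacrum=sacrum, sacrum_velocity=sacrum_v, sacrum_acceleration=sacrum_a,
        com=com, com_velocity=com_v, orientations=orientations,
        gates=course, gate_directions=dirs,
        gate_crossing_times=cross_t, gate_crossing_distances=cross_d,
        static_windows=static_windows, body=model, true_azimuth=true_azimuth,
        meta={"mean_speed": mean_speed, "rate": rate, "seed": seed,
              "pass_distance": pass_distance, "lean_max": float(np.max(np.abs(lean))),
              "hip_flexion": hip_flexion, "knee_flexion": knee_flexion},
    )


def _sensor_positions(gt: GroundTruth) -> dict[str, np.ndarray]:
    """World position of each sensor from the kinematic chain."""
    model = gt.body
    ljc = gt.sacrum.values
    o = gt.orientations
    chain = bm._chain_points(gt.orientations, model)
    pos = {"sacrum": ljc}
    pos["sternum"] = ljc + o["trunk"].rotations.apply([0.0, 0.30, 0.0])
    pos["helmet"] = (ljc + o["trunk"].rotations.apply([0.0, model.trunk_length, 0.0])
                     + o["head"].rotations.apply([0.0, 0.12, 0.0]))
    for side in ("l", "r"):
        hip, knee = chain[side][0], chain[side][1]
        pos[f"thigh_{side}"] = ljc + hip + chain[side][3].apply(
            [0.0, -0.5 * model.thigh_length, 0.0])
        pos[f"shank_{side}"] = ljc + knee + chain[side][4].apply(
            [0.0, -0.5 * model.shank_length, 0.0])
    return pos


def _gyro_from_orientations(tl: OrientationTimeline) -> np.ndarray:
    """Body rates whose left-rule exponential integration reproduces ``tl``."""
    rot = tl.rotations
    dt = tl.dt
    rel = rot[:-1].inv() * rot[1:]
    omega = rel.as_rotvec() / dt
    return np.vstack([omega, omega[-1]])


def synthesize_imu(gt: GroundTruth, noise: SensorNoiseModel) -> tuple[dict, dict]:
    """Accelerometer and gyroscope signals for every sensor location.

    Specific force in the sensor frame is ``R^T (a - g_vec)``; angular
    velocity is the per-step rotation increment of the segment orientation
    timeline, so noise-free strap-down re-integration is exact.  White
    noise and a constant per-sensor gyro bias are added on top.
    """
    rng = np.random.default_rng(noise.seed)
    g_vec = gravity_vector()
    t = gt.t
    dt = float(t[1] - t[0])
    positions = _sensor_positions(gt)
    accel, gyro = {}, {}
    for sensor, segment in bm.SENSOR_TO_SEGMENT.items():
        rot = gt.orientations[segment].rotations
        if sensor == "sacrum":
            a_world = gt.sacrum_acceleration.values
        else:
            a_world = np.gradient(np.gradient(positions[sensor], dt, axis=0),
                                  dt, axis=0)
        f = rot.inv().apply(a_world - g_vec)
        w = _gyro_from_orientations(gt.orientations[segment])
        bias = rng.normal(0.0, noise.gyro_bias, 3) if noise.gyro_bias > 0 else np.zeros(3)
        f = f + rng.normal(0.0, noise.accel_sigma, f.shape) if noise.accel_sigma > 0 else f
        w = w + bias
        w = w + rng.normal(0.0, noise.gyro_sigma, w.shape) if noise.gyro_sigma > 0 else w
        accel[sensor] = TimeSeries3D(t.copy(), f, FRAME_SENSOR)
        gyro[sensor] = TimeSeries3D(t.copy(), w, FRAME_SENSOR)
    return accel, gyro


def magnet_field_norm(distances: np.ndarray,
                      dipole_constant: float = DIPOLE_CONSTANT,
                      min_distance: float = DIPOLE_MIN_DISTANCE) -> np.ndarray:
    """Forward dipole model of the field norm at given magnet distances."""
    r = np.maximum(np.asarray(distances, float), min_distance)
    return 1.0 + dipole_constant / r**3


def synthesize_magnetometer(gt: GroundTruth, noise: SensorNoiseModel,
                            dipole_constant: float = DIPOLE_CONSTANT,
                            min_distance: float = DIPOLE_MIN_DISTANCE) -> TimeSeries3D:
    """125 Hz sacrum magnetometer signal.

    The field norm is the ambient field (calibrated to 1) plus a 1/r^3
    dipole contribution from every gate magnet; the vector points along a
    fixed ambient direction rotated into the sensor frame.  Sampling at
    125 Hz deliberately under-samples the sharp peak of a fast pass.
    """
    rng = np.random.default_rng(noise.seed + 104729)
    idx = np.arange(0, len(gt.t), MAG_DECIMATION)
    t = gt.t[idx]
    pos = gt.sacrum.values[idx]
    norm = np.ones(len(idx))
    for g in gt.gates.positions:
        d = np.linalg.norm(pos - g, axis=1)
        near = d < 10.0
        if np.any(near):
            norm[near] += dipole_constant / np.maximum(d[near], min_distance)**3
    rot = gt.orientations["pelvis"].rotations[idx]
    vec = rot.inv().apply(EARTH_FIELD_DIR) * norm[:, None]
    if noise.mag_sigma > 0:
        vec = vec + rng.normal(0.0, noise.mag_sigma, vec.shape)
    return TimeSeries3D(t, vec, FRAME_SENSOR)


def simulate_run(spec: CourseSpec | None = None,
                 noise: SensorNoiseModel | None = None,
                 seed: int = 0, **trajectory_kwargs) -> tuple[GroundTruth, SensorSet]:
    """Generate a complete simulated run: course, ground truth, sensors."""
    spec = spec or CourseSpec()
    course = generate_course(spec, seed=seed)
    gt = generate_trajectory(course, seed=seed + 1, **trajectory_kwargs)
    noise = noise if noise is not None else SensorNoiseModel(seed=seed + 2)
    accel, gyro = synthesize_imu(gt, noise)
    mag = synthesize_magnetometer(gt, noise)
    return gt, SensorSet(accel=accel, gyro=gyro, mag=mag)
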