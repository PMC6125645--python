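"""15-state extended Kalman smoother and the two-pass fusion pipeline.

State vector (per axis triplets): 3D position, 3D speed, 3D acceleration,
3D position offset, and 3 small Euler angles representing residual
orientation drift of the strap-down estimate.  A constant-acceleration
model (white jerk) drives the transitions; measurements are

* the gravity-corrected global-frame acceleration at every sample, with
  the drift angles entering as a small-angle rotation of the measured
  specific force (gravity leakage is the dominant effect of orientation
  drift, so the lever arm is ``z - g_vec``),
* zero velocity during the static start/finish postures,
* sparse position anchors at gate crossings, observing position plus the
  position-offset states.

The small-angle measurement Jacobian is evaluated at the *measured*
acceleration, which makes the filter exactly linear in the state given
the data — forward filtering plus RTS smoothing is then the exact MAP
estimate of the corresponding linear-Gaussian problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import body_model as bm
from .anchors import (
    AnchorSet,
    GateCrossing,
    MatchResult,
    assign_turn_numbers,
    detect_gate_crossings,
    distance_from_intensity,
    estimate_azimuth,
    estimate_relative_anchor,
    match_anchors,
)
from .core import (
    FRAME_EARTH,
    FRAME_INERTIAL,
    GRAVITY,
    InvalidInputError,
    MatchingFailedError,
    OrientationTimeline,
    PipelineError,
    TimeSeries3D,
    butterworth_lowpass,
    gravity_vector,
    rotation_about_y,
    skew,
    three_point_derivative,
)
from .strapdown import (
    detect_static_windows,
    estimate_gyro_bias,
    global_linear_acceleration,
    initial_orientation_from_accel,
    strapdown_orientation,
)
from .synthetic import SensorSet

N_STATES = 15
POS = slice(0, 3)
VEL = slice(3, 6)
ACC = slice(6, 9)
OFF = slice(9, 12)
DRIFT = slice(12, 15)


@dataclass
class EKSConfig:
    """Smoother noise densities and measurement sigmas.

    Process noises are continuous-time densities; measurement sigmas are
    per-sample standard deviations.  The anchor sigma shrinks from 1 m on
    the first fusion pass to 0.1 m on the second, reflecting the improved
    relative anchor estimates.
    """

    jerk_psd: float = 50.0          # (m/s^3)^2 / Hz
    offset_rw_psd: float = 1e-8     # m^2 / s
    drift_rw_psd: float = 5e-6      # rad^2 / s
    accel_noise: float = 0.03       # m/s^2
    zupt_sigma: float = 0.01        # m/s
    anchor_sigma_first: float = 1.0
    anchor_sigma_second: float = 0.1
    init_pos_sigma: float = 1e-3
    init_vel_sigma: float = 1e-3
    init_acc_sigma: float = 1.0
    init_offset_sigma: float = 0.05
    init_drift_sigma: float = 0.02
    anchor_gate_sigma: float = 5.0  # innovation gate, in sigmas
    gravity: float = GRAVITY

    def __post_init__(self):
        for name in ("jerk_psd", "offset_rw_psd", "drift_rw_psd", "accel_noise",
                     "zupt_sigma", "anchor_sigma_first", "anchor_sigma_second"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if self.anchor_sigma_second >= self.anchor_sigma_first:
            raise InvalidInputError("second-pass anchor sigma must be smaller")


@dataclass
class EKSResult:
    """Smoothed state timeline with covariance traces and innovation log."""

    t: np.ndarray
    states: np.ndarray              # (n, 15) smoothed means
    cov_diag: np.ndarray            # (n, 15) smoothed variances
    trace_filtered: np.ndarray
    trace_smoothed: np.ndarray
    innovations: list[dict] = field(default_factory=list)
    frame_id: str = FRAME_INERTIAL

    def position(self) -> TimeSeries3D:
        return TimeSeries3D(self.t.copy(), self.states[:, POS], self.frame_id)

    def velocity(self) -> TimeSeries3D:
        return TimeSeries3D(self.t.copy(), self.states[:, VEL], self.frame_id)

    def acceleration(self) -> TimeSeries3D:
        return TimeSeries3D(self.t.copy(), self.states[:, ACC], self.frame_id)


def transition_matrices(dt: float, cfg: EKSConfig) -> tuple[np.ndarray, np.ndarray]:
    """Discrete constant-acceleration transition and process noise."""
    F = np.eye(N_STATES)
    for k in range(3):
        F[k, 3 + k] = dt
        F[k, 6 + k] = 0.5 * dt * dt
        F[3 + k, 6 + k] = dt
    q = cfg.jerk_psd
    blk = q * np.array([
        [dt**5 / 20.0, dt**4 / 8.0, dt**3 / 6.0],
        [dt**4 / 8.0, dt**3 / 3.0, dt**2 / 2.0],
        [dt**3 / 6.0, dt**2 / 2.0, dt],
    ])
    Q = np.zeros((N_STATES, N_STATES))
    for k in range(3):
        idx = np.array([k, 3 + k, 6 + k])
        Q[np.ix_(idx, idx)] = blk
    Q[OFF, OFF] += np.eye(3) * cfg.offset_rw_psd * dt
    Q[DRIFT, DRIFT] += np.eye(3) * cfg.drift_rw_psd * dt
    return F, Q


def accel_measurement_matrix(z: np.ndarray, gravity: float = GRAVITY) -> np.ndarray:
    """Jacobian of the acceleration observation, evaluated at the data."""
    H = np.zeros((3, N_STATES))
    H[:, ACC] = np.eye(3)
    H[:, DRIFT] = -skew(np.asarray(z) - gravity_vector(gravity))
    return H


def zupt_measurement_matrix() -> np.ndarray:
    H = np.zeros((3, N_STATES))
    H[:, VEL] = np.eye(3)
    return H


def anchor_measurement_matrix() -> np.ndarray:
    H = np.zeros((3, N_STATES))
    H[:, POS] = np.eye(3)
    H[:, OFF] = np.eye(3)
    return H


def initial_covariance(cfg: EKSConfig) -> np.ndarray:
    P0 = np.zeros((N_STATES, N_STATES))
    P0[POS, POS] = np.eye(3) * cfg.init_pos_sigma**2
    P0[VEL, VEL] = np.eye(3) * cfg.init_vel_sigma**2
    P0[ACC, ACC] = np.eye(3) * cfg.init_acc_sigma**2
    P0[OFF, OFF] = np.eye(3) * cfg.init_offset_sigma**2
    P0[DRIFT, DRIFT] = np.eye(3) * cfg.init_drift_sigma**2
    return P0


def _update(x, P, H, z, sigma):
    R = np.eye(len(z)) * sigma**2
    S = H @ P @ H.T + R
    e = z - H @ x
    K = np.linalg.solve(S, H @ P).T
    x = x + K @ e
    IKH = np.eye(N_STATES) - K @ H
    P = IKH @ P @ IKH.T + K @ R @ K.T
    return x, 0.5 * (P + P.T), e, S


def eks_smooth(a_global: TimeSeries3D,
               static_windows: list[tuple[float, float]],
               anchor_updates: list[tuple[float, np.ndarray]],
               cfg: EKSConfig,
               anchor_sigma: float | None = None,
               x0: np.ndarray | None = None,
               P0: np.ndarray | None = None) -> EKSResult:
    """Forward Kalman filter plus RTS fixed-interval smoothing.

    ``anchor_updates`` is a list of ``(time, position)`` measurements,
    applied at the nearest sample; anchors whose normalised innovation
    exceeds the configured gate are logged and skipped.  Returns smoothed
    states at every input sample.
    """
    if not np.all(np.isfinite(a_global.values)):
        raise InvalidInputError("non-finite acceleration input")
    n = len(a_global)
    dt = a_global.dt
    t = a_global.t
    sigma_anchor = cfg.anchor_sigma_first if anchor_sigma is None else anchor_sigma

    F, Q = transition_matrices(dt, cfg)
    Hz = zupt_measurement_matrix()
    Ha = anchor_measurement_matrix()
    g_vec = gravity_vector(cfg.gravity)

    static = np.zeros(n, dtype=bool)
    for t0, t1 in static_windows:
        static |= (t >= t0) & (t <= t1)
    if not static.any():
        raise InvalidInputError("static windows are empty")

    anchors_at: dict[int, list[np.ndarray]] = {}
    for tm, pos in anchor_updates:
        if not (t[0] - dt <= tm <= t[-1] + dt):
            raise InvalidInputError("anchor time outside the recording")
        k = int(np.clip(round((tm - t[0]) / dt), 0, n - 1))
        anchors_at.setdefault(k, []).append(np.asarray(pos, float))

    x = np.zeros(N_STATES) if x0 is None else np.asarray(x0, float).copy()
    P = initial_covariance(cfg) if P0 is None else np.asarray(P0, float).copy()

    xf = np.empty((n, N_STATES))
    Pf = np.empty((n, N_STATES, N_STATES))
    xp = np.empty((n, N_STATES))
    Pp = np.empty((n, N_STATES, N_STATES))
    innovations: list[dict] = []
    z_all = a_global.values
    gate2 = cfg.anchor_gate_sigma**2 * 3.0

    for k in range(n):
        if k > 0:
            x = F @ x
            P = F @ P @ F.T + Q
            P = 0.5 * (P + P.T)
        xp[k] = x
        Pp[k] = P

        z = z_all[k]
        H = accel_measurement_matrix(z, cfg.gravity)
        x, P, _, _ = _update(x, P, H, z, cfg.accel_noise)
        if static[k]:
            x, P, e, S = _update(x, P, Hz, np.zeros(3), cfg.zupt_sigma)
        for pos in anchors_at.get(k, ()):
            S = Ha @ P @ Ha.T + np.eye(3) * sigma_anchor**2
            e = pos - Ha @ x
            d2 = float(e @ np.linalg.solve(S, e))
            accepted = d2 <= gate2
            innovations.append({"t": float(t[k]), "type": "anchor",
                                "residual": float(np.linalg.norm(e)),
                                "accepted": accepted})
            if accepted:
                x, P, _, _ = _update(x, P, Ha, pos, sigma_anchor)
        xf[k] = x
        Pf[k] = P

    # RTS backward pass
    xs = np.empty_like(xf)
    cov_diag = np.empty((n, N_STATES))
    trace_s = np.empty(n)
    xs[n - 1] = xf[n - 1]
    Ps = Pf[n - 1]
    cov_diag[n - 1] = np.diag(Ps)
    trace_s[n - 1] = np.trace(Ps)
    for k in range(n - 2, -1, -1):
        C = Pf[k] @ F.T
        G = np.linalg.solve(Pp[k + 1], C.T).T
        xs[k] = xf[k] + G @ (xs[k + 1] - xp[k + 1])
        Ps = Pf[k] + G @ (Ps - Pp[k + 1]) @ G.T
        Ps = 0.5 * (Ps + Ps.T)
        cov_diag[k] = np.diag(Ps)
        trace_s[k] = np.trace(Ps)

    return EKSResult(t=t.copy(), states=xs, cov_diag=cov_diag,
                     trace_filtered=np.einsum("kii->k", Pf),
                     trace_smoothed=trace_s, innovations=innovations,
                     frame_id=a_global.frame_id)


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class PipelineConfig:
    """Configuration of the full anchor-fusion pipeline."""

    eks: EKSConfig = field(default_factory=EKSConfig)
    detection_threshold: float = 1.05
    min_peak_separation: float = 1.0
    plane_half_window: float = 0.4
    complementary_tau: float = 30.0
    complementary_gate: float = 0.05
    com_filter_cutoff: float = 5.0
    com_filter_order: int = 2
    dh_keep_every: int = 3  # anchor thinning factor in DH mode
    trunk_axis: tuple = (0.0, 1.0, 0.0)


@dataclass
class PipelineResult:
    """Final trajectories and the intermediate estimation products."""

    sacrum_position: TimeSeries3D
    sacrum_velocity: TimeSeries3D
    com_position: TimeSeries3D
    com_velocity: TimeSeries3D
    azimuth: float
    offset: np.ndarray
    crossings: list[GateCrossing]
    match_first: MatchResult
    match_second: MatchResult
    eks_first: EKSResult
    eks_second: EKSResult
    pass1_sacrum: TimeSeries3D
    static_windows: list[tuple[float, float]]
    orientations: dict[str, OrientationTimeline]
    relative_com: TimeSeries3D


def absolute_com(refined_ljc: TimeSeries3D, rel_com: TimeSeries3D,
                 azimuth: float = 0.0, cutoff: float = 5.0,
                 order: int = 2) -> tuple[TimeSeries3D, TimeSeries3D]:
    """Absolute CoM position and velocity.

    Adds the (azimuth-aligned) body-model CoM offset to the refined sacrum
    trajectory, differentiates with the three-point rule and low-passes
    both signals with a zero-phase Butterworth filter.
    """
    if len(refined_ljc) != len(rel_com):
        raise InvalidInputError("trajectory and relative CoM length mismatch")
    rel = rotation_about_y(azimuth).apply(rel_com.values)
    p = TimeSeries3D(refined_ljc.t.copy(), refined_ljc.values + rel,
                     refined_ljc.frame_id)
    v = three_point_derivative(p)
    p = butterworth_lowpass(p, order, cutoff)
    v = butterworth_lowpass(v, order, cutoff)
    return p, v


def _estimate_anchor_cloud(crossings, p_ljc, v_ljc, ski, cfg):
    """Relative anchor estimation for every usable crossing."""
    usable = []
    for c in crossings:
        try:
            plane = bm.fit_snow_plane(ski, c.t, cfg.plane_half_window,
                                      toward=p_ljc.interp(c.t))
            estimate_relative_anchor(c, p_ljc, v_ljc, plane)
        except InvalidInputError:
            continue
        usable.append(c)
    return usable


def run_fusion_pipeline(sensors: SensorSet, gate_survey: AnchorSet,
                        body: bm.BodySegmentModel | None = None,
                        cfg: PipelineConfig | None = None,
                        dh_mode: bool = False) -> PipelineResult:
    """Estimate the absolute CoM trajectory of one run.

    Pass 0 integrates the sacrum acceleration with zero-velocity updates
    only; its drifting trajectory is good enough to estimate relative
    anchor points and match them to the surveyed gates, which fixes the
    azimuth/offset between the athlete's inertial frame and the survey
    frame.  Pass 1 fuses the matched anchors at 1 m sigma; the anchors are
    then re-estimated from the refined trajectory, re-matched with
    absolute-position features, and fused again at 0.1 m sigma (pass 2).
    ``dh_mode`` keeps only every third surveyed gate as an anchor,
    emulating downhill gate distances.
    """
    body = body or bm.BodySegmentModel()
    cfg = cfg or PipelineConfig()

    # --- calibration and strap-down per segment
    sac_gyro = sensors.gyro["sacrum"]
    statics = detect_static_windows(sac_gyro, acc=sensors.accel["sacrum"])
    if len(statics) < 2:
        raise PipelineError("could not find static start and finish postures")
    start_win, end_win = statics[0], statics[-1]

    orientations: dict[str, OrientationTimeline] = {}
    gyro_cal: dict[str, TimeSeries3D] = {}
    for sensor, segment in bm.SENSOR_TO_SEGMENT.items():
        gyro = sensors.gyro[sensor]
        acc = sensors.accel[sensor]
        bias = estimate_gyro_bias(gyro.slice_time(*start_win))
        gyro = gyro.with_values(gyro.values - bias)
        gyro_cal[sensor] = gyro
        init = initial_orientation_from_accel(acc.slice_time(*start_win))
        orientations[segment] = strapdown_orientation(
            gyro, init, acc=acc, time_constant=cfg.complementary_tau,
            accel_gate=cfg.complementary_gate)

    a_global = global_linear_acceleration(sensors.accel["sacrum"],
                                          orientations["pelvis"],
                                          gravity=cfg.eks.gravity)

    # --- pass 0: inertial-only sacrum trajectory (frame J)
    eks0 = eks_smooth(a_global, [start_win, end_win], [], cfg.eks)
    p0, v0 = eks0.position(), eks0.velocity()

    rel_com = bm.relative_com(orientations, body)
    contacts = bm.snow_contact_points(orientations, p0, body)
    ski0 = bm.ski_line(*contacts)

    # --- gate crossings
    crossings = detect_gate_crossings(sensors.mag, cfg.detection_threshold,
                                      cfg.min_peak_separation)
    if len(crossings) < 2:
        raise PipelineError("fewer than two gate crossings detected")
    for c in crossings:
        c.r_norm = distance_from_intensity(c.peak_norm)
        c.direction = bm.turn_direction_at(c.t, gyro_cal["sacrum"],
                                           np.asarray(cfg.trunk_axis))
    numbers = assign_turn_numbers([c.direction for c in crossings])
    for c, num in zip(crossings, numbers):
        c.turn_number = num

    # --- first anchor estimation + matching (J -> G transform)
    usable = _estimate_anchor_cloud(crossings, p0, v0, ski0, cfg)
    if len(usable) < 2:
        raise PipelineError("too few usable gate crossings")
    gm = np.array([c.anchor_estimate for c in usable])
    alpha = estimate_azimuth(gate_survey, gm)
    rot = rotation_about_y(alpha)
    try:
        match1 = match_anchors(gate_survey, rot.apply(gm),
                               [c.direction for c in usable],
                               [c.turn_number for c in usable],
                               stage="first", azimuth=alpha)
    except MatchingFailedError as exc:
        raise PipelineError("first-pass anchor matching failed") from exc

    def anchor_updates_from(pairs, cross_list, r_rot):
        updates = []
        for m, n_idx in pairs:
            if dh_mode and n_idx % cfg.dh_keep_every != 0:
                continue
            c = cross_list[m]
            r_vec = r_rot.apply(c.r_vec) if r_rot is not None else c.r_vec
            updates.append((c.t, gate_survey.positions[n_idx] - r_vec))
            c.matched_gate = int(gate_survey.gate_ids[n_idx])
        return updates

    # --- pass 1: fuse anchors at 1 m sigma, in the survey frame G
    a_G = TimeSeries3D(a_global.t.copy(), rot.apply(a_global.values), FRAME_EARTH)
    x0 = np.zeros(N_STATES)
    x0[POS] = match1.offset
    P0 = initial_covariance(cfg.eks)
    P0[POS, POS] = np.eye(3) * 25.0
    eks1 = eks_smooth(a_G, [start_win, end_win],
                      anchor_updates_from(match1.pairs, usable, rot),
                      cfg.eks, anchor_sigma=cfg.eks.anchor_sigma_first,
                      x0=x0, P0=P0)
    p1, v1 = eks1.position(), eks1.velocity()

    # --- re-estimate anchors from the refined trajectory, re-match
    orientations_G = {k: OrientationTimeline(tl.t, rot * tl.rotations, FRAME_EARTH)
                      for k, tl in orientations.items()}
    ski1 = bm.ski_line(*bm.snow_contact_points(orientations_G, p1, body))
    crossings2 = [GateCrossing(index=c.index, t=c.t, peak_norm=c.peak_norm,
                               r_norm=c.r_norm, direction=c.direction,
                               turn_number=c.turn_number) for c in usable]
    usable2 = _estimate_anchor_cloud(crossings2, p1, v1, ski1, cfg)
    if len(usable2) < 2:
        raise PipelineError("too few usable crossings on the second pass")
    gm2 = np.array([c.anchor_estimate for c in usable2])
    try:
        match2 = match_anchors(gate_survey, gm2,
                               [c.direction for c in usable2],
                               [c.turn_number for c in usable2],
                               stage="second", azimuth=alpha)
    except MatchingFailedError as exc:
        raise PipelineError("second-pass anchor matching failed") from exc

    # --- pass 2: fuse at 0.1 m sigma
    eks2 = eks_smooth(a_G, [start_win, end_win],
                      anchor_updates_from(match2.pairs, usable2, None),
                      cfg.eks, anchor_sigma=cfg.eks.anchor_sigma_second,
                      x0=x0, P0=P0)
    p2, v2 = eks2.position(), eks2.velocity()

    com_p, com_v = absolute_com(p2, rel_com, azimuth=alpha,
                                cutoff=cfg.com_filter_cutoff,
                                order=cfg.com_filter_order)

    return PipelineResult(
        sacrum_position=p2, sacrum_velocity=v2,
        com_position=com_p, com_velocity=com_v,
        azimuth=alpha, offset=match1.offset,
        crossings=usable2, match_first=match1, match_second=match2,
        eks_first=eks1, eks_second=eks2, pass1_sacrum=p1,
        static_windows=[start_win, end_win],
        orientations=orientations, relative_com=rel_com,
    )
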