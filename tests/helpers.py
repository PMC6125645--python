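"""Independent oracles used by the test suite.

The batch smoother here solves the full linear-Gaussian MAP problem in
information form with a sparse direct solve — an algorithmically
independent route to the same estimate the forward/backward recursive
smoother computes.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from skifuse.core import TimeSeries3D
from skifuse.fusion import (
    N_STATES,
    EKSConfig,
    accel_measurement_matrix,
    anchor_measurement_matrix,
    initial_covariance,
    transition_matrices,
    zupt_measurement_matrix,
)


def batch_map_states(a_global: TimeSeries3D,
                     static_windows: list[tuple[float, float]],
                     anchor_updates: list[tuple[float, np.ndarray]],
                     cfg: EKSConfig,
                     anchor_sigma: float,
                     x0: np.ndarray | None = None,
                     P0: np.ndarray | None = None) -> np.ndarray:
    """MAP trajectory of the smoother's linear-Gaussian problem.

    Assembles the joint information matrix over all time steps (prior +
    process + measurement terms) and solves it directly.
    """
    n = len(a_global)
    t = a_global.t
    dt = a_global.dt
    F, Q = transition_matrices(dt, cfg)
    Qinv = np.linalg.inv(Q)
    P0 = initial_covariance(cfg) if P0 is None else np.asarray(P0, float)
    x0 = np.zeros(N_STATES) if x0 is None else np.asarray(x0, float)

    static = np.zeros(n, dtype=bool)
    for t0, t1 in static_windows:
        static |= (t >= t0) & (t <= t1)

    anchors_at: dict[int, list[np.ndarray]] = {}
    for tm, pos in anchor_updates:
        k = int(np.clip(round((tm - t[0]) / dt), 0, n - 1))
        anchors_at.setdefault(k, []).append(np.asarray(pos, float))

    dim = n * N_STATES
    Lam = sp.lil_matrix((dim, dim))
    eta = np.zeros(dim)

    def add_block(i, j, block):
        Lam[i * N_STATES:(i + 1) * N_STATES, j * N_STATES:(j + 1) * N_STATES] += block

    P0inv = np.linalg.inv(P0)
    add_block(0, 0, P0inv)
    eta[:N_STATES] += P0inv @ x0

    FtQi = F.T @ Qinv
    for k in range(n - 1):
        add_block(k, k, FtQi @ F)
        add_block(k, k + 1, -FtQi)
        add_block(k + 1, k, -FtQi.T)
        add_block(k + 1, k + 1, Qinv)

    Hz = zupt_measurement_matrix()
    Ha = anchor_measurement_matrix()
    for k in range(n):
        z = a_global.values[k]
        H = accel_measurement_matrix(z, cfg.gravity)
        w = 1.0 / cfg.accel_noise**2
        add_block(k, k, w * H.T @ H)
        eta[k * N_STATES:(k + 1) * N_STATES] += w * H.T @ z
        if static[k]:
            w = 1.0 / cfg.zupt_sigma**2
            add_block(k, k, w * Hz.T @ Hz)
        for pos in anchors_at.get(k, ()):
            w = 1.0 / anchor_sigma**2
            add_block(k, k, w * Ha.T @ Ha)
            eta[k * N_STATES:(k + 1) * N_STATES] += w * Ha.T @ pos

    A = Lam.tocsc()
    lu = spla.splu(A)
    sol = lu.solve(eta)
    # the information form squares the problem's condition number, so plain
    # float64 refinement stalls; extended-precision residuals let it converge
    A_ld = A.astype(np.longdouble)
    eta_ld = eta.astype(np.longdouble)
    for _ in range(6):
        r = eta_ld - A_ld @ sol.astype(np.longdouble)
        sol = sol + lu.solve(np.asarray(r, dtype=float))
    return sol.reshape(n, N_STATES)


def random_lgssm_instance(rng: np.random.Generator, one_dimensional: bool = False):
    """A random smoothing problem: smooth acceleration, ZUPTs, sparse anchors."""
    n = int(rng.integers(120, 280))
    # keep the instances numerically well posed: coarse-ish steps limit the
    # eigenvalue spread of the triple-integrator process noise (~dt^-4) and
    # a bounded horizon keeps the sparsely anchored position observable,
    # so that two float64 solution routes can agree to tight tolerance
    dt = float(rng.uniform(0.08, 0.15))
    t = np.arange(n) * dt
    freq = rng.uniform(0.2, 1.0, 3)
    amp = rng.uniform(0.5, 6.0, 3)
    phase = rng.uniform(0, 2 * np.pi, 3)
    acc = amp * np.sin(2 * np.pi * freq * t[:, None] + phase)
    acc += rng.normal(0, 0.05, acc.shape)
    if one_dimensional:
        acc[:, 1:] = 0.0
    a_global = TimeSeries3D(t, acc, "J")

    static = [(0.0, float(t[max(5, n // 20)]))]
    n_anchors = int(rng.integers(2, 6))
    times = np.sort(rng.uniform(t[5], t[-5], n_anchors))
    anchors = []
    for tm in times:
        pos = rng.normal(0, 5.0, 3)
        if one_dimensional:
            pos[1:] = 0.0
        anchors.append((float(tm), pos))

    cfg = EKSConfig(jerk_psd=float(rng.uniform(1.0, 10.0)),
                    offset_rw_psd=1e-4, drift_rw_psd=1e-5,
                    accel_noise=0.1, zupt_sigma=0.05,
                    init_pos_sigma=0.1, init_vel_sigma=0.1,
                    init_drift_sigma=0.01, anchor_gate_sigma=1e9)
    sigma = float(rng.uniform(0.2, 1.5))
    return a_global, static, anchors, cfg, sigma


def matching_robustness_trial(seed: int, number_weight: float = 1.0):
    """One 30-gate correspondence problem: unknown azimuth/translation, one
    missed gate, one spurious detection, anchor noise bounded by 1 m.

    Returns (ok, n_correct, n_real) where ok requires zero false
    assignments of real detections, at most one real detection lost to a
    duplicate collision, and the spurious detection either unmatched or
    matched to the single gate that has no real detection of its own.
    """
    import skifuse.anchors as anc
    import skifuse.synthetic as syn
    from skifuse.core import rotation_about_y

    rng = np.random.default_rng(seed)
    gn = syn.generate_course(syn.CourseSpec(), seed=seed)
    dirs = anc.course_turn_directions(gn)
    n = len(gn)

    missed = int(rng.integers(0, n))
    keep = [i for i in range(n) if i != missed]
    noise = rng.uniform(-1.0, 1.0, (len(keep), 3)) * np.array([0.5, 0.3, 0.5])
    gm_world = gn.positions[keep] + noise
    det_dirs = [dirs[i] for i in keep]

    j = int(rng.integers(1, len(keep) - 1))
    spurious = 0.5 * (gm_world[j - 1] + gm_world[j]) + rng.normal(0.0, 1.0, 3)
    gm_world = np.insert(gm_world, j, spurious, axis=0)
    det_dirs.insert(j, str(rng.choice(["left", "right"])))
    numbers = anc.assign_turn_numbers(det_dirs)

    azimuth = float(rng.uniform(-0.9 * np.pi, 0.9 * np.pi))
    translation = rng.uniform(-300, 300, 3)
    gm_j = rotation_about_y(-azimuth).apply(gm_world - translation)

    alpha = anc.estimate_azimuth(gn, gm_j)
    gm_rot = rotation_about_y(alpha).apply(gm_j)
    first = anc.match_anchors(gn, gm_rot, det_dirs, numbers, stage="first",
                              number_weight=number_weight)
    second = anc.match_anchors(gn, gm_rot + first.offset, det_dirs, numbers,
                               stage="second", number_weight=number_weight)

    mapping = dict(second.pairs)
    true_gate = {m: keep[m if m < j else m - 1]
                 for m in range(len(gm_world)) if m != j}
    false_assignments = sum(1 for m, k in true_gate.items()
                            if m in mapping and mapping[m] != k)
    n_correct = sum(1 for m, k in true_gate.items() if mapping.get(m) == k)
    spurious_ok = mapping.get(j, missed) == missed
    ok = (false_assignments == 0 and n_correct >= len(true_gate) - 1
          and spurious_ok)
    return ok, n_correct, len(true_gate)
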