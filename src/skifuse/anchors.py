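"""Gate-crossing detection and anchor-point estimation / matching.

A buried magnet at each gate perturbs the Earth field measured by the
sacrum magnetometer; the field-norm peak marks the gate crossing and its
magnitude encodes the sacrum-to-magnet distance.  Each crossing is turned
into an *estimated* anchor point by projecting the sacrum onto the locally
fitted snow plane and stepping laterally, perpendicular to the velocity,
toward the turn side.  Estimated anchors (in the inertial frame J) are
then matched to the surveyed gate positions (Earth frame G) by an
azimuth-and-offset alignment of the two point clouds followed by a
nearest-neighbour feature matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.signal import find_peaks

from .body_model import SnowPlane
from .core import (
    AmbiguousAzimuthError,
    InvalidInputError,
    MatchingFailedError,
    TimeSeries3D,
    horizontal_angle,
    rotation_about_y,
)

#: default weights that make the mixed-unit feature norm meaningful: a
#: left/right disagreement costs 2 * LR_WEIGHT meters, one turn-number step
#: costs NUMBER_WEIGHT meters.  The number weight is deliberately small —
#: a tie-breaker, not a geometry override: a spurious detection that breaks
#: left/right alternation shifts every later turn number by two while
#: *preserving* direction parity, so a heavy number feature would drag the
#: whole tail of the course onto gates two positions away.
LR_WEIGHT = 10.0
NUMBER_WEIGHT = 1.0
DETECTION_THRESHOLD = 1.05
MIN_PEAK_SEPARATION = 1.0


@dataclass
class AnchorSet:
    """Ordered surveyed gate (magnet) positions in the Earth frame."""

    positions: np.ndarray
    gate_ids: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InvalidInputError("positions must be (N, 3)")
        if len(self.positions) < 2:
            raise InvalidInputError("need at least two gates")
        gaps = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        if gaps.min() <= 5.0:
            raise InvalidInputError("consecutive gates closer than 5 m")
        if self.gate_ids is None:
            self.gate_ids = np.arange(1, len(self.positions) + 1)
        else:
            self.gate_ids = np.asarray(self.gate_ids)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class GateCrossing:
    """One detected gate crossing and its derived anchor geometry."""

    index: int
    t: float
    peak_norm: float
    r_norm: float | None = None
    direction: str | None = None
    turn_number: int | None = None
    d_vec: np.ndarray | None = None
    x_vec: np.ndarray | None = None
    r_vec: np.ndarray | None = None
    projected_point: np.ndarray | None = None
    plane: SnowPlane | None = None
    anchor_estimate: np.ndarray | None = None
    degenerate: bool = False
    matched_gate: int | None = None


@dataclass
class MatchResult:
    """Estimated-to-surveyed anchor correspondence and J->G transform."""

    azimuth: float
    offset: np.ndarray
    pairs: list[tuple[int, int]]  # (m index, n index), both 0-based
    unmatched_m: list[int] = field(default_factory=list)
    unmatched_n: list[int] = field(default_factory=list)


def detect_gate_crossings(mag: TimeSeries3D,
                          threshold: float = DETECTION_THRESHOLD,
                          min_separation: float = MIN_PEAK_SEPARATION) -> list[GateCrossing]:
    """Local maxima of the magnetometer field norm above ``threshold``.

    Operates on the native (125 Hz) samples so that the known peak
    under-sampling of fast passes is preserved; peaks closer than
    ``min_separation`` seconds keep only the larger one.
    """
    norm = mag.norm()
    distance = max(1, int(round(min_separation * mag.rate)))
    peaks, _ = find_peaks(norm, height=threshold, distance=distance)
    return [GateCrossing(index=m, t=float(mag.t[i]), peak_norm=float(norm[i]))
            for m, i in enumerate(peaks)]


def distance_from_intensity(b_norm: float) -> float:
    """Sacrum-to-magnet distance from the peak field norm.

    Piecewise-linear lab calibration of the magnet's dipole decay, with
    the field normalised so that ``||B|| = 1`` far from any magnet:

        ||r|| = -0.4 ||B|| + 1.0      if ||B|| < 1.62
        ||r|| = -0.062 ||B|| + 0.452  otherwise

    clamped below at zero.
    """
    b = float(b_norm)
    if b < 1.0:
        raise InvalidInputError("field norm below calibrated baseline 1.0")
    r = -0.4 * b + 1.0 if b < 1.62 else -0.062 * b + 0.452
    return max(r, 0.0)


def assign_turn_numbers(directions: list[str]) -> list[int]:
    """Turn numbers for detected crossings.

    The first detected anchor point is turn number one and no two
    consecutive left or right turns can occur; a detected direction that
    violates alternation increments the number by two (a gap is assumed).
    """
    numbers = []
    for i, d in enumerate(directions):
        if i == 0:
            numbers.append(1)
        elif d != directions[i - 1]:
            numbers.append(numbers[-1] + 1)
        else:
            numbers.append(numbers[-1] + 2)
    return numbers


def estimate_relative_anchor(crossing: GateCrossing, p_ljc: TimeSeries3D,
                             v_ljc: TimeSeries3D, plane: SnowPlane) -> GateCrossing:
    """Fill in the anchor geometry of a crossing (in the trajectory frame).

    The sacrum is projected onto the snow plane (d); the remaining lateral
    leg (x) lies on the plane, perpendicular to the velocity, pointing to
    the gate side given by the turn direction; the estimated anchor is
    ``p_ljc(t_m) + d + x``.  If the total distance from the field intensity
    is shorter than the plane distance (possible with an under-sampled
    peak) the lateral leg collapses to zero and the crossing is flagged.
    """
    if crossing.r_norm is None:
        crossing.r_norm = distance_from_intensity(crossing.peak_norm)
    if crossing.direction not in ("left", "right"):
        raise InvalidInputError("crossing needs a turn direction")
    p = p_ljc.interp(crossing.t)
    v = v_ljc.interp(crossing.t)
    n = plane.normal
    p_hat = p + np.dot(plane.point - p, n) * n
    d = p_hat - p
    d_norm = np.linalg.norm(d)
    r2 = crossing.r_norm**2 - d_norm**2
    if r2 <= 0:
        x = np.zeros(3)
        crossing.degenerate = True
    else:
        cross = (np.cross(d, v) if crossing.direction == "right"
                 else np.cross(v, d))
        nc = np.linalg.norm(cross)
        if nc < 1e-12:
            raise InvalidInputError("velocity parallel to plane offset")
        x = np.sqrt(r2) * cross / nc
    crossing.projected_point = p_hat
    crossing.plane = plane
    crossing.d_vec = d
    crossing.x_vec = x
    crossing.r_vec = d + x
    crossing.anchor_estimate = p + crossing.r_vec
    return crossing


def course_turn_directions(anchors: AnchorSet) -> list[str]:
    """Geometric turn direction at each surveyed gate.

    Sign of the vertical component of the horizontal cross product of the
    incoming and outgoing gate-to-gate displacements (positive = turning
    left in a Y-up right-handed frame).  End gates copy the alternation.
    """
    g = anchors.positions
    n = len(g)
    dirs: list[str | None] = [None] * n
    for i in range(1, n - 1):
        a = g[i] - g[i - 1]
        b = g[i + 1] - g[i]
        turn = a[2] * b[0] - a[0] * b[2]  # (a x b) . Y with horizontal parts
        dirs[i] = "left" if turn >= 0 else "right"
    flip = {"left": "right", "right": "left"}
    dirs[0] = flip[dirs[1]]
    dirs[-1] = flip[dirs[-2]]
    return dirs


def _principal_direction(points: np.ndarray) -> np.ndarray:
    """First horizontal principal component, oriented first -> last point."""
    xz = points[:, [0, 2]] - points[:, [0, 2]].mean(axis=0)
    cov = xz.T @ xz / len(xz)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1.2 * max(evals[0], 1e-300):
        raise AmbiguousAzimuthError("point cloud too isotropic for azimuth")
    pc = evecs[:, 1]
    span = points[-1, [0, 2]] - points[0, [0, 2]]
    if np.dot(pc, span) < 0:
        pc = -pc
    return np.array([pc[0], 0.0, pc[1]])


def estimate_azimuth(gn: AnchorSet, gm: np.ndarray) -> float:
    """Azimuth angle aligning the estimated cloud with the surveyed one.

    Angle between the first horizontal principal components of the two
    clouds, signed so that ``rotation_about_y(alpha)`` applied to the
    estimated anchors brings them parallel to the surveyed course, with
    both principal directions oriented in the start-to-finish sense.
    """
    gm = np.asarray(gm, dtype=float)
    if len(gm) < 2:
        raise InvalidInputError("need at least two estimated anchors")
    pc_n = _principal_direction(gn.positions)
    pc_m = _principal_direction(gm)
    alpha = horizontal_angle(pc_n) - horizontal_angle(pc_m)
    return float(np.arctan2(np.sin(alpha), np.cos(alpha)))


def _features(points: np.ndarray, directions: list[str], numbers: list[int],
              stage: str, lr_weight: float, number_weight: float) -> np.ndarray:
    lr = np.array([1.0 if d == "left" else -1.0 for d in directions])
    num = np.asarray(numbers, dtype=float)
    if stage == "first":
        nxt = np.diff(points, axis=0)
        fwd = np.vstack([nxt, nxt[-1]])   # last point duplicates its predecessor diff
        bwd = np.vstack([nxt[0], nxt])    # first point duplicates its successor diff
        return np.column_stack([fwd, bwd, lr_weight * lr, number_weight * num])
    if stage == "second":
        return np.column_stack([points, lr_weight * lr, number_weight * num])
    raise InvalidInputError("stage must be 'first' or 'second'")


def match_anchors(gn: AnchorSet, gm: np.ndarray, directions: list[str],
                  turn_numbers: list[int], stage: str = "first",
                  gn_directions: list[str] | None = None,
                  lr_weight: float = LR_WEIGHT,
                  number_weight: float = NUMBER_WEIGHT,
                  azimuth: float = 0.0) -> MatchResult:
    """Nearest-neighbour anchor matching with duplicate removal.

    ``gm`` must already be azimuth-aligned (stage 'first', relative
    features) or azimuth-and-offset corrected (stage 'second', absolute
    position features).  Each estimated anchor picks the surveyed gate
    with the closest feature vector; matchings sharing a surveyed gate are
    removed; the translation offset is the component-wise median position
    difference of the surviving pairs.
    """
    gm = np.asarray(gm, dtype=float)
    if len(gm) < 1:
        raise MatchingFailedError("no estimated anchors")
    if gn_directions is None:
        gn_directions = course_turn_directions(gn)
    gn_numbers = list(range(1, len(gn) + 1))

    f_n = _features(gn.positions, gn_directions, gn_numbers, stage,
                    lr_weight, number_weight)
    f_m = _features(gm, directions, turn_numbers, stage,
                    lr_weight, number_weight)

    k_m = np.array([int(np.argmin(np.linalg.norm(f_n - fm, axis=1))) for fm in f_m])
    counts = np.bincount(k_m, minlength=len(gn))
    pairs = [(m, int(n)) for m, n in enumerate(k_m) if counts[n] == 1]
    if not pairs:
        raise MatchingFailedError("all matchings were duplicates")

    diffs = np.array([gn.positions[n] - gm[m] for m, n in pairs])
    offset = np.median(diffs, axis=0)
    matched_m = {m for m, _ in pairs}
    matched_n = {n for _, n in pairs}
    return MatchResult(
        azimuth=azimuth,
        offset=offset,
        pairs=pairs,
        unmatched_m=[m for m in range(len(gm)) if m not in matched_m],
        unmatched_n=[n for n in range(len(gn)) if n not in matched_n],
    )


def brute_force_match(gn: AnchorSet, gm: np.ndarray, directions: list[str],
                      turn_numbers: list[int], stage: str = "second",
                      gn_directions: list[str] | None = None,
                      lr_weight: float = LR_WEIGHT,
                      number_weight: float = NUMBER_WEIGHT) -> list[tuple[int, int]]:
    """Exhaustive injective assignment minimising the total feature cost.

    Exponential in the number of gates; intended as an independent check
    for small courses (N <= 8), not for production use.
    """
    gm = np.asarray(gm, dtype=float)
    if gn_directions is None:
        gn_directions = course_turn_directions(gn)
    f_n = _features(gn.positions, gn_directions, list(range(1, len(gn) + 1)),
                    stage, lr_weight, number_weight)
    f_m = _features(gm, directions, turn_numbers, stage, lr_weight, number_weight)
    m_count, n_count = len(f_m), len(f_n)
    best_cost, best = np.inf, None
    for perm in permutations(range(n_count), m_count):
        cost = sum(np.linalg.norm(f_n[n] - f_m[m]) for m, n in enumerate(perm))
        if cost < best_cost:
            best_cost, best = cost, perm
    return [(m, n) for m, n in enumerate(best)]


def apply_transform(points: np.ndarray, azimuth: float, offset: np.ndarray) -> np.ndarray:
    """J -> G: rotate about the vertical axis by ``azimuth``, then translate."""
    rot = rotation_about_y(azimuth)
    return rot.apply(np.asarray(points, float)) + np.asarray(offset, float)
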