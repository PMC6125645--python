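"""Relative body kinematics rooted at the lumbar joint center (LJC).

The pipeline identifies the sacrum sensor position with the LJC, so every
relative quantity (whole-body CoM, ankle positions, ski contact points) is
expressed with respect to the sacrum trajectory.  The segment model is a
seven-segment chain (pelvis, trunk incl. arms, head, two thighs, two
shanks incl. feet) with literature-style mass fractions; only its
interface is contractual — the pipeline needs CoM-relative-to-LJC and the
ankle/contact points, not a particular anthropometry.

Axis conventions inside a segment frame: x forward, y up along the
segment's longitudinal axis, z to the (athlete's) right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from .core import (
    DegenerateGeometryError,
    InvalidInputError,
    OrientationTimeline,
    TimeSeries3D,
)

SEGMENTS = ("pelvis", "trunk", "head", "thigh_l", "thigh_r", "shank_l", "shank_r")

#: sensor location -> segment driven by that sensor
SENSOR_TO_SEGMENT = {
    "sacrum": "pelvis",
    "sternum": "trunk",
    "helmet": "head",
    "thigh_l": "thigh_l",
    "thigh_r": "thigh_r",
    "shank_l": "shank_l",
    "shank_r": "shank_r",
}


@dataclass
class BodySegmentModel:
    """Seven-segment surrogate body model.

    Mass fractions must sum to one; arms are folded into the trunk and
    feet into the shanks.  Lengths in meters, offsets expressed in the
    parent segment frame.
    """

    thigh_length: float = 0.45
    shank_length: float = 0.43
    contact_offset: float = 0.15  # ankle -> snow along distal shank axis
    hip_half_width: float = 0.09
    hip_drop: float = 0.10  # LJC down to hip-center level
    trunk_com_height: float = 0.22  # above LJC along trunk axis
    trunk_length: float = 0.50
    head_com_offset: float = 0.08  # above trunk top
    pelvis_com_drop: float = 0.05
    segment_com_ratio: float = 0.433  # thigh/shank CoM from proximal joint
    mass_fractions: dict = field(default_factory=lambda: {
        "pelvis": 0.142, "trunk": 0.436, "head": 0.081,
        "thigh_l": 0.100, "thigh_r": 0.100,
        "shank_l": 0.0705, "shank_r": 0.0705,
    })

    def __post_init__(self):
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError(f"mass fractions sum to {total}, expected 1")
        for name, val in (("thigh_length", self.thigh_length),
                          ("shank_length", self.shank_length)):
            if val <= 0:
                raise InvalidInputError(f"{name} must be positive")

    def hip_offset(self, side: str) -> np.ndarray:
        z = self.hip_half_width if side == "r" else -self.hip_half_width
        return np.array([0.0, -self.hip_drop, z])


@dataclass
class SnowPlane:
    """Snow surface patch: a point on the plane and its unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, float)
        self.normal = np.asarray(self.normal, float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            raise InvalidInputError("plane normal must be unit length")

    def signed_distance(self, p: np.ndarray) -> float:
        return float(np.dot(np.asarray(p) - self.point, self.normal))


@dataclass
class TurnEvent:
    """One turn, delimited by two consecutive turn switches."""

    start: float
    end: float
    direction: str  # 'left' | 'right'
    number: int

    def __post_init__(self):
        if self.start >= self.end:
            raise InvalidInputError("turn start must precede end")
        if self.direction not in ("left", "right"):
            raise InvalidInputError("direction must be 'left' or 'right'")


def _check_segments(orientations: dict) -> None:
    missing = [s for s in SEGMENTS if s not in orientations]
    if missing:
        raise InvalidInputError(f"missing segment orientations: {missing}")


def _chain_points(orientations: dict[str, OrientationTimeline],
                  model: BodySegmentModel):
    """Joint positions of the lower-limb chain relative to the LJC (frame J)."""
    out = {}
    for side in ("l", "r"):
        r_pelvis = orientations["pelvis"].rotations
        r_thigh = orientations[f"thigh_{side}"].rotations
        r_shank = orientations[f"shank_{side}"].rotations
        hip = r_pelvis.apply(model.hip_offset(side))
        knee = hip + r_thigh.apply([0.0, -model.thigh_length, 0.0])
        ankle = knee + r_shank.apply([0.0, -model.shank_length, 0.0])
        out[side] = (hip, knee, ankle, r_thigh, r_shank)
    return out


def relative_com(orientations: dict[str, OrientationTimeline],
                 model: BodySegmentModel) -> TimeSeries3D:
    """Whole-body CoM relative to the LJC, in the global inertial frame.

    Mass-fraction weighted sum of the segment CoM positions, each obtained
    from the kinematic chain rooted at the LJC.
    """
    _check_segments(orientations)
    t = orientations["pelvis"].t
    for tl in orientations.values():
        if len(tl) != t.size:
            raise InvalidInputError("segment orientation timelines must be aligned")
    frame = orientations["pelvis"].frame_id

    chain = _chain_points(orientations, model)
    r_pelvis = orientations["pelvis"].rotations
    r_trunk = orientations["trunk"].rotations
    r_head = orientations["head"].rotations

    coms = {
        "pelvis": r_pelvis.apply([0.0, -model.pelvis_com_drop, 0.0]),
        "trunk": r_trunk.apply([0.0, model.trunk_com_height, 0.0]),
        "head": (r_trunk.apply([0.0, model.trunk_length, 0.0])
                 + r_head.apply([0.0, model.head_com_offset, 0.0])),
    }
    for side in ("l", "r"):
        hip, knee, _, r_thigh, r_shank = chain[side]
        coms[f"thigh_{side}"] = hip + r_thigh.apply(
            [0.0, -model.segment_com_ratio * model.thigh_length, 0.0])
        coms[f"shank_{side}"] = knee + r_shank.apply(
            [0.0, -model.segment_com_ratio * model.shank_length, 0.0])

    total = np.zeros((t.size, 3))
    for name, pos in coms.items():
        total += model.mass_fractions[name] * pos
    return TimeSeries3D(t.copy(), total, frame)


def ankle_positions(orientations: dict[str, OrientationTimeline],
                    ljc_trajectory: TimeSeries3D,
                    model: BodySegmentModel):
    """Left and right ankle joint centers in the global frame."""
    _check_segments(orientations)
    if len(ljc_trajectory) != len(orientations["pelvis"]):
        raise InvalidInputError("trajectory and orientations must be aligned")
    chain = _chain_points(orientations, model)
    out = []
    for side in ("l", "r"):
        ankle = chain[side][2] + ljc_trajectory.values
        out.append(TimeSeries3D(ljc_trajectory.t.copy(), ankle, ljc_trajectory.frame_id))
    return tuple(out)


def snow_contact_points(orientations: dict[str, OrientationTimeline],
                        ljc_trajectory: TimeSeries3D,
                        model: BodySegmentModel):
    """Ski-snow contact point of each foot.

    Located ``model.contact_offset`` (0.15 m) distally from the ankle joint
    center along the shank's longitudinal axis.
    """
    _check_segments(orientations)
    chain = _chain_points(orientations, model)
    left, right = ankle_positions(orientations, ljc_trajectory, model)
    out = []
    for side, ankle_ts in (("l", left), ("r", right)):
        r_shank = chain[side][4]
        contact = ankle_ts.values + r_shank.apply([0.0, -model.contact_offset, 0.0])
        out.append(ankle_ts.with_values(contact))
    return tuple(out)


def ski_line(left: TimeSeries3D, right: TimeSeries3D) -> TimeSeries3D:
    """Average ski line: sample-wise midpoint of the two contact points."""
    if len(left) != len(right):
        raise InvalidInputError("contact point series length mismatch")
    return left.with_values(0.5 * (left.values + right.values))


def leg_vertical_extent(model: BodySegmentModel, hip_flexion: float,
                        knee_flexion: float) -> float:
    """Vertical LJC-to-snow distance for a symmetric flexed posture.

    Hip flexion rotates the thigh forward from vertical; knee flexion
    rotates the shank back toward vertical by ``knee_flexion - hip_flexion``
    relative to the thigh.  Used by the simulator so that the synthetic
    contact points land on the snow surface.
    """
    shank_tilt = hip_flexion - knee_flexion
    return (model.hip_drop
            + model.thigh_length * np.cos(hip_flexion)
            + (model.shank_length + model.contact_offset) * np.cos(shank_tilt))


def fit_snow_plane(line: TimeSeries3D, t_m: float, half_window: float = 0.4,
                   toward: np.ndarray | None = None) -> SnowPlane:
    """Total-least-squares plane through the ski line around a gate crossing.

    Uses the window ``[t_m - half_window, t_m + half_window]``; the normal
    is the smallest principal component of the windowed points and the
    plane point is the window centroid.  ``toward`` (e.g. the LJC position)
    orients the normal to the skier side.
    """
    if t_m - half_window < line.t[0] - 1e-9 or t_m + half_window > line.t[-1] + 1e-9:
        raise InvalidInputError("plane-fit window not fully inside the recording")
    window = line.slice_time(t_m - half_window, t_m + half_window)
    pts = window.values
    if len(pts) < 3:
        raise DegenerateGeometryError("need >= 3 points for a plane fit")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1e-300):
        raise DegenerateGeometryError("ski-line window is collinear")
    normal = vt[2]
    if toward is not None:
        if np.dot(np.asarray(toward) - centroid, normal) < 0:
            normal = -normal
    elif normal[1] < 0:  # default: point up-ish
        normal = -normal
    return SnowPlane(centroid, normal)


def turn_direction_at(t: float, sacrum_gyro: TimeSeries3D,
                      trunk_axis: np.ndarray = (0.0, 1.0, 0.0)) -> str:
    """Turn direction at time ``t`` from the sacrum angular velocity.

    'right' if the angular velocity component along the trunk's
    longitudinal axis is negative at the gate crossing, 'left' otherwise
    (ties break to 'left').  ``trunk_axis`` is expressed in the gyro's
    frame and defaults to the sensor's longitudinal axis.
    """
    if not (sacrum_gyro.t[0] <= t <= sacrum_gyro.t[-1]):
        raise InvalidInputError("time outside the recording")
    omega = sacrum_gyro.interp(t)
    return "right" if float(np.dot(omega, np.asarray(trunk_axis, float))) < 0 else "left"


def detect_turn_switches(com: TimeSeries3D, left_ankle: TimeSeries3D,
                         right_ankle: TimeSeries3D,
                         sacrum_gyro: TimeSeries3D | None = None,
                         trunk_axis: np.ndarray = (0.0, 1.0, 0.0),
                         min_excursion: float = 0.02) -> list[TurnEvent]:
    """Turn events from the equal-ankle-distance criterion.

    A turn switch occurs where ``||left - CoM|| - ||right - CoM||`` changes
    sign; the crossing time is refined by linear interpolation.  Crossings
    whose neighbourhood never exceeds ``min_excursion`` (meters of distance
    asymmetry) are discarded as noise, which suppresses chatter during the
    static, symmetric start/finish postures.  Directions alternate and are
    anchored on the sacrum gyro when provided.
    """
    if not (len(com) == len(left_ankle) == len(right_ankle)):
        raise InvalidInputError("series must be aligned")
    delta = (np.linalg.norm(left_ankle.values - com.values, axis=1)
             - np.linalg.norm(right_ankle.values - com.values, axis=1))
    sign = np.sign(delta)
    idx = np.flatnonzero((sign[:-1] != sign[1:]) & (sign[:-1] != 0))
    if idx.size == 0:
        return []

    # refine and filter by excursion on both sides
    t = com.t
    switches = []
    for k, i in enumerate(idx):
        d0, d1 = delta[i], delta[i + 1]
        tc = t[i] + (t[i + 1] - t[i]) * d0 / (d0 - d1) if d0 != d1 else t[i]
        lo = idx[k - 1] if k > 0 else 0
        hi = idx[k + 1] if k + 1 < idx.size else delta.size - 1
        if (np.max(np.abs(delta[lo:i + 1])) >= min_excursion
                and np.max(np.abs(delta[i:hi + 1])) >= min_excursion):
            switches.append(tc)
    if len(switches) < 2:
        return []

    events = []
    for n, (t0, t1) in enumerate(zip(switches[:-1], switches[1:]), start=1):
        events.append(TurnEvent(t0, t1, "left", n))

    # assign alternating directions, anchored on the gyro if available
    first_dir = "left"
    if sacrum_gyro is not None:
        mid = 0.5 * (events[0].start + events[0].end)
        first_dir = turn_direction_at(mid, sacrum_gyro, trunk_axis)
    flip = {"left": "right", "right": "left"}
    d = first_dir
    for ev in events:
        ev.direction = d
        d = flip[d]
    return events
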