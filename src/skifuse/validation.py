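"""Agreement metrics against a reference trajectory.

Errors are decomposed in the local skiing frame built from the reference
velocity (x along the velocity, z = x cross up, y completing the triad).
'Accuracy' is the per-run mean of an error signal and 'precision' its
per-run standard deviation; overall values average the per-run ones
rather than pooling samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body_model import TurnEvent
from .core import (
    GRAVITY,
    InvalidInputError,
    TimeSeries3D,
    gravity_vector,
    local_skiing_frames,
)


@dataclass
class AxisStats:
    mean: np.ndarray
    std: np.ndarray


@dataclass
class RunErrorReport:
    """Per-run trajectory and speed error summary."""

    d: TimeSeries3D                 # position error, global frame
    d_local: TimeSeries3D           # position error in the skiing frame
    d_tot: np.ndarray               # ||d||
    s_tot: np.ndarray               # speed-norm error
    s_local: TimeSeries3D           # velocity error in the skiing frame
    position_accuracy: float        # mean of d_tot
    position_precision: float       # std of d_tot
    speed_accuracy: float           # mean of s_tot
    speed_precision: float          # std of s_tot
    position_axis: AxisStats        # per-axis stats of d_local
    speed_axis: AxisStats           # per-axis stats of s_local


@dataclass
class TurnParameters:
    """Speed/distance performance parameters of one turn."""

    v_in: float
    v_out: float
    d_in: float
    d_out: float
    d_cross: float
    l_tot: float
    turn_number: int = 0
    gate_id: int | None = None
    crossing_inside_turn: bool = True


@dataclass
class BlandAltman:
    """Bland-Altman agreement: mean difference and 95% limits."""

    mean: float
    lower_loa: float
    upper_loa: float
    differences: np.ndarray


def trajectory_errors(est: TimeSeries3D, ref: TimeSeries3D,
                      est_v: TimeSeries3D, ref_v: TimeSeries3D,
                      gravity: float = GRAVITY) -> RunErrorReport:
    """Position and speed errors of one run against a reference.

    The total speed error is the difference of the speed norms (so a pure
    direction error yields zero); the per-axis speed error rotates the
    velocity-difference vector into the skiing frame, hence the axis
    components need not recombine into the total.
    """
    if len(est) != len(ref) or len(est_v) != len(ref_v) or len(est) != len(est_v):
        raise InvalidInputError("series must share a common time base")
    if abs(est.t[0] - ref.t[0]) > 1e-9 or abs(est.dt - ref.dt) > 1e-12:
        raise InvalidInputError("series must share a common time base")

    d = est.values - ref.values
    dv = est_v.values - ref_v.values
    frames = local_skiing_frames(ref_v.values, gravity_vector(gravity))
    d_local = np.einsum("nij,nj->ni", frames.transpose(0, 2, 1), d)
    s_local = np.einsum("nij,nj->ni", frames.transpose(0, 2, 1), dv)
    d_tot = np.linalg.norm(d, axis=1)
    s_tot = np.linalg.norm(est_v.values, axis=1) - np.linalg.norm(ref_v.values, axis=1)

    return RunErrorReport(
        d=TimeSeries3D(est.t.copy(), d, ref.frame_id),
        d_local=TimeSeries3D(est.t.copy(), d_local, "S"),
        d_tot=d_tot, s_tot=s_tot,
        s_local=TimeSeries3D(est.t.copy(), s_local, "S"),
        position_accuracy=float(d_tot.mean()),
        position_precision=float(d_tot.std(ddof=0)),
        speed_accuracy=float(s_tot.mean()),
        speed_precision=float(s_tot.std(ddof=0)),
        position_axis=AxisStats(d_local.mean(axis=0), d_local.std(axis=0)),
        speed_axis=AxisStats(s_local.mean(axis=0), s_local.std(axis=0)),
    )


def summarize_runs(reports: list[RunErrorReport]) -> dict:
    """Overall accuracy/precision: the average of the per-run values."""
    if not reports:
        raise InvalidInputError("no runs to summarise")
    return {
        "position_accuracy": float(np.mean([r.position_accuracy for r in reports])),
        "position_precision": float(np.mean([r.position_precision for r in reports])),
        "speed_accuracy": float(np.mean([r.speed_accuracy for r in reports])),
        "speed_precision": float(np.mean([r.speed_precision for r in reports])),
    }


def turn_parameters(com: TimeSeries3D, speed: TimeSeries3D, turn: TurnEvent,
                    gate: np.ndarray, t_cross: float | None = None) -> TurnParameters:
    """Performance parameters of one turn relative to its gate.

    Entrance/exit speeds and gate distances are taken at the two turn
    switches; ``l_tot`` is the polyline length of the CoM over the turn;
    ``d_cross`` the CoM-gate distance at the gate crossing (closest
    approach when no crossing time is supplied).
    """
    if len(com) != len(speed):
        raise InvalidInputError("com and speed must be aligned")
    if turn.start < com.t[0] or turn.end > com.t[-1]:
        raise InvalidInputError("turn window outside the recording")
    gate = np.asarray(gate, float)

    p_in = com.interp(turn.start)
    p_out = com.interp(turn.end)
    v_in = float(np.linalg.norm(speed.interp(turn.start)))
    v_out = float(np.linalg.norm(speed.interp(turn.end)))

    mask = (com.t >= turn.start) & (com.t <= turn.end)
    seg = com.values[mask]
    l_tot = float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))

    inside = True
    if t_cross is None:
        d_cross = float(np.min(np.linalg.norm(com.values - gate, axis=1)))
    else:
        d_cross = float(np.linalg.norm(com.interp(t_cross) - gate))
        inside = turn.start <= t_cross <= turn.end

    return TurnParameters(
        v_in=v_in, v_out=v_out,
        d_in=float(np.linalg.norm(p_in - gate)),
        d_out=float(np.linalg.norm(p_out - gate)),
        d_cross=d_cross, l_tot=l_tot,
        turn_number=turn.number, crossing_inside_turn=inside,
    )


def bland_altman(pairs, loa_multiplier: float = 1.96) -> BlandAltman:
    """Limits of agreement of (estimate, reference) pairs.

    Differences are estimate minus reference; limits are the mean
    difference +/- 1.96 sample standard deviations (n-1 denominator).
    """
    pairs = np.asarray(pairs, float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 2:
        raise InvalidInputError("need at least two (estimate, reference) pairs")
    diffs = pairs[:, 0] - pairs[:, 1]
    mean = float(diffs.mean())
    spread = loa_multiplier * float(diffs.std(ddof=1))
    return BlandAltman(mean=mean, lower_loa=mean - spread,
                       upper_loa=mean + spread, differences=diffs)
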