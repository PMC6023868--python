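"""Trajectory kinematics and per-trial decision extraction.

Raw overhead-camera positions (cm, ~10–12 Hz) are median-smoothed and
differenced into speed (body lengths per second, FL/s), acceleration
(FL/s²) and a dimensionless turning arc.  The turning arc is the absolute
angle θ ∈ [0, π] between successive velocity vectors passed through sin(θ),
mapping straight swimming to 0 and a right-angle turn to 1; turns beyond
90° (rare in practice, <2 % of observations in this assay) are counted in a
diagnostic but transformed with the same sine.

Decision scoring distinguishes the decision time T_D — decision-zone entry
to arm entry — from the time to act T_A — gate opening to arm entry, which
includes any social recruitment while the fish was still in the holding
area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .maze import MazeGeometry, Zone, arm_entrance_crossing, classify_zones

__all__ = [
    "Track",
    "KinematicSeries",
    "DecisionRecord",
    "smooth_positions",
    "compute_kinematics",
    "extract_decision",
    "assign_decision_order",
    "tracks_to_csv",
    "tracks_from_csv",
    "decisions_to_frame",
]


@dataclass
class Track:
    """One fish's time-stamped positional trajectory in maze coordinates."""

    fish_id: str
    t: np.ndarray  # s, strictly increasing
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    sampling_rate: float  # Hz
    body_length: float = 3.5  # cm

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal lengths")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class KinematicSeries:
    """Differenced kinematic variables for one track.

    Lengths follow the differencing order: speed and cumulative distance
    have n−1 entries, acceleration and turning arc n−2.  Turning arcs at
    zero-length velocity steps are NaN (direction undefined).
    """

    speed: np.ndarray  # FL/s
    acceleration: np.ndarray  # FL/s²
    turning_arc: np.ndarray  # sin(θ), in [0, 1] or NaN
    cumulative_distance: np.ndarray  # FL
    n_sharp_turns: int = 0  # diagnostic: count of θ > π/2


@dataclass
class DecisionRecord:
    """Scored outcome of one fish in one trial."""

    fish_id: str
    chosen_arm: Optional[Zone] = None
    correct: Optional[bool] = None
    t_a: Optional[float] = None  # s, gate to arm entry
    t_d: Optional[float] = None  # s, zone entry to arm entry
    decision_order: Optional[int] = None  # 1-based rank among deciders

    @property
    def decided(self) -> bool:
        return self.chosen_arm is not None


def smooth_positions(track: Track) -> Track:
    """Running-median smoothing with a 3-step window.

    Interior points become the median of themselves and their two
    neighbours; the two endpoints pass through unchanged (window truncation
    is not defined by the 3-step rule, and pass-through preserves length).
    """
    if len(track) < 3:
        raise ValueError("smoothing requires at least 3 frames")

    def med3(v: np.ndarray) -> np.ndarray:
        out = v.copy()
        out[1:-1] = np.median(np.column_stack([v[:-2], v[1:-1], v[2:]]), axis=1)
        return out

    return replace(track, x=med3(track.x), y=med3(track.y))


def compute_kinematics(track: Track) -> KinematicSeries:
    """Differentiate a (smoothed) track into speed, acceleration and turning.

    speed_i = |p_{i+1} − p_i| · rate / body_length  (FL/s); acceleration is
    the first difference of speed scaled back to seconds; the turning arc is
    sin of the absolute angle between successive displacement vectors.
    """
    if track.body_length <= 0:
        raise ValueError("body_length must be > 0")
    p = track.positions
    if len(p) < 2:
        raise ValueError("kinematics require at least 2 frames")
    rate = track.sampling_rate
    d = np.diff(p, axis=0)  # cm per step
    step_len = np.hypot(d[:, 0], d[:, 1])
    speed = step_len * rate / track.body_length
    acceleration = np.diff(speed) * rate
    cumdist = np.cumsum(step_len) / track.body_length

    # angle between successive displacement vectors, undefined on zero steps
    v1, v2 = d[:-1], d[1:]
    n1, n2 = step_len[:-1], step_len[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))
    theta[(n1 == 0) | (n2 == 0)] = np.nan
    turning_arc = np.sin(theta)
    n_sharp = int(np.nansum(theta > np.pi / 2))
    return KinematicSeries(speed, acceleration, turning_arc, cumdist, n_sharp)


def extract_decision(
    track: Track,
    geom: MazeGeometry,
    gate_time: float,
    target_arm: Zone,
) -> DecisionRecord:
    """Score one fish: arm choice, correctness, T_A and T_D.

    T_D runs from the first decision-zone entry to the first arm-entrance
    crossing; T_A from ``gate_time`` to that crossing.  A fish that never
    crosses into an arm yields a record with only its id filled in.
    """
    if len(track) == 0:
        raise ValueError("empty track")
    if gate_time > track.t[-1]:
        raise ValueError("gate_time is after the end of the track")
    crossing = arm_entrance_crossing(track.positions, geom)
    if crossing is None:
        return DecisionRecord(fish_id=track.fish_id)
    arm, idx = crossing
    labels = classify_zones(track.positions, geom)
    entry_idx = next(i for i, z in enumerate(labels) if z is Zone.DECISION)
    t_cross = float(track.t[idx])
    return DecisionRecord(
        fish_id=track.fish_id,
        chosen_arm=arm,
        correct=(arm == target_arm),
        t_a=t_cross - gate_time,
        t_d=t_cross - float(track.t[entry_idx]),
    )


def assign_decision_order(records: list[DecisionRecord]) -> list[DecisionRecord]:
    """Rank deciders by arm-crossing time (= gate time + T_A) within a trial.

    Ties are broken by fish id so downstream social tallies are
    well-defined.  Non-deciders keep order None.  Records are modified in
    place and returned.
    """
    deciders = [r for r in records if r.decided]
    deciders.sort(key=lambda r: (r.t_a, str(r.fish_id)))
    for rank, r in enumerate(deciders, start=1):
        r.decision_order = rank
    return records


def tracks_to_csv(tracks: dict[str, list[Track]], path: str) -> None:
    """Write trajectories as tidy CSV (trial, fish, frame, t, x, y)."""
    rows = []
    for trial_id, trial_tracks in tracks.items():
        for tr in trial_tracks:
            rows.append(
                pd.DataFrame(
                    {
                        "trial": trial_id,
                        "fish": tr.fish_id,
                        "frame": np.arange(len(tr)),
                        "t": tr.t,
                        "x": tr.x,
                        "y": tr.y,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def tracks_from_csv(
    path: str, sampling_rate: float = 10.0, body_length: float = 3.5
) -> dict[str, list[Track]]:
    """Read a tidy trajectory CSV back into per-trial Track lists."""
    df = pd.read_csv(path)
    required = {"trial", "fish", "t", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    out: dict[str, list[Track]] = {}
    for (trial_id, fish_id), g in df.groupby(["trial", "fish"], sort=True):
        g = g.sort_values("t")
        out.setdefault(str(trial_id), []).append(
            Track(
                fish_id=str(fish_id),
                t=g["t"].to_numpy(),
                x=g["x"].to_numpy(),
                y=g["y"].to_numpy(),
                sampling_rate=sampling_rate,
                body_length=body_length,
            )
        )
    return out


def decisions_to_frame(records: dict[str, list[DecisionRecord]]) -> pd.DataFrame:
    """Flatten per-trial decision records into a tidy table."""
    rows = []
    for trial_id, recs in records.items():
        for r in recs:
            rows.append(
                {
                    "trial": trial_id,
                    "fish": r.fish_id,
                    "arm": r.chosen_arm.value if r.chosen_arm else "",
                    "correct": "" if r.correct is None else bool(r.correct),
                    "t_a": np.nan if r.t_a is None else r.t_a,
                    "t_d": np.nan if r.t_d is None else r.t_d,
                    "order": -1 if r.decision_order is None else r.decision_order,
                }
            )
    return pd.DataFrame(rows)
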