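"""Y-maze geometry and zone classification.

The maze is modelled in 2D (overhead-camera view) with the origin at the
centre of the circular decision zone and lengths in centimetres.  The
holding arm points along −y; the two destination arms point at ±120° from
it, giving the three-fold symmetry of a Y-maze.  Each arm is a rectangle of
``arm_length × arm_width`` abutting the decision-zone circle; the water
depth is ignored.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "Zone",
    "MazeGeometry",
    "classify_zone",
    "classify_zones",
    "arm_entrance_crossing",
]


class Zone(enum.Enum):
    """Mutually exclusive regions of the maze."""

    HOLDING = "HOLDING"
    DECISION = "DECISION"
    ARM_LEFT = "ARM_LEFT"
    ARM_RIGHT = "ARM_RIGHT"
    OUTSIDE = "OUTSIDE"


def _unit(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a)])


@dataclass(frozen=True)
class MazeGeometry:
    """Dimensions and axes of the Y-maze, in cm.

    Defaults are the physical apparatus: arms 46 cm long and 23 cm wide
    around a decision zone 46 cm in diameter.  ``leader_boundary_extension``
    extends the region in which leader silhouettes remain visible back
    toward the holding arm (13.8 cm in the group-size experiment, 0
    otherwise).
    """

    arm_length: float = 46.0
    arm_width: float = 23.0
    decision_zone_diameter: float = 46.0
    leader_boundary_extension: float = 0.0

    def __post_init__(self) -> None:
        for name in ("arm_length", "arm_width", "decision_zone_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.leader_boundary_extension < 0:
            raise ValueError("leader_boundary_extension must be >= 0")

    @property
    def zone_radius(self) -> float:
        return self.decision_zone_diameter / 2.0

    # Holding arm along -y; destination arms ±120° away from it.
    @property
    def holding_axis(self) -> np.ndarray:
        return _unit(-90.0)

    @property
    def left_arm_axis(self) -> np.ndarray:
        return _unit(150.0)

    @property
    def right_arm_axis(self) -> np.ndarray:
        return _unit(30.0)

    def arm_axis(self, arm: Zone) -> np.ndarray:
        if arm is Zone.ARM_LEFT:
            return self.left_arm_axis
        if arm is Zone.ARM_RIGHT:
            return self.right_arm_axis
        raise ValueError(f"not a destination arm: {arm}")

    def arm_entrance(self, arm: Zone) -> np.ndarray:
        """Centre of the line where an arm meets the decision zone."""
        return self.arm_axis(arm) * self.zone_radius

    def holding_point(self, offset: float = 3.0) -> np.ndarray:
        """A resting position inside the holding arm, ``offset`` cm behind
        the decision-zone boundary."""
        return self.holding_axis * (self.zone_radius + offset)

    @classmethod
    def from_dict(cls, d: dict) -> "MazeGeometry":
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path: str) -> "MazeGeometry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _in_arm_rect(p: np.ndarray, axis: np.ndarray, geom: MazeGeometry) -> np.ndarray:
    """Vectorised membership test for the rectangle of one arm.

    The rectangle spans projections [zone_radius, zone_radius + arm_length]
    along ``axis`` with half-width arm_width/2.
    """
    along = p @ axis
    perp = p @ np.array([-axis[1], axis[0]])
    r = geom.zone_radius
    return (
        (along >= r)
        & (along <= r + geom.arm_length)
        & (np.abs(perp) <= geom.arm_width / 2.0)
    )


def classify_zones(points: np.ndarray, geom: MazeGeometry) -> np.ndarray:
    """Classify an (n, 2) array of points; returns an object array of Zone.

    Precedence on overlap: DECISION > ARM_LEFT > ARM_RIGHT > HOLDING.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[None, :]
    labels = np.full(len(points), Zone.OUTSIDE, dtype=object)
    in_zone = np.einsum("ij,ij->i", points, points) <= geom.zone_radius**2
    left = _in_arm_rect(points, geom.left_arm_axis, geom)
    right = _in_arm_rect(points, geom.right_arm_axis, geom)
    hold = _in_arm_rect(points, geom.holding_axis, geom)
    labels[hold] = Zone.HOLDING
    labels[right] = Zone.ARM_RIGHT
    labels[left] = Zone.ARM_LEFT
    labels[in_zone] = Zone.DECISION
    return labels


def classify_zone(p, geom: MazeGeometry) -> Zone:
    """Classify a single 2D point (cm) into its maze zone."""
    return classify_zones(np.asarray(p, dtype=float), geom)[0]


def arm_entrance_crossing(track, geom: MazeGeometry):
    """First DECISION→ARM transition of a trajectory.

    Parameters
    ----------
    track : object with ``positions`` -> (n, 2) array, or an (n, 2) array.
    geom : MazeGeometry

    Returns
    -------
    (Zone, int) or None
        The arm entered and the frame index of the first in-arm frame, or
        None when the fish never crosses from the decision zone into an arm.
        Re-entries after the first crossing are ignored: the assay scores a
        single choice per trial.
    """
    pos = getattr(track, "positions", track)
    pos = np.asarray(pos, dtype=float)
    if pos.size == 0:
        raise ValueError("empty track")
    labels = classify_zones(pos, geom)
    for i in range(1, len(labels)):
        if labels[i - 1] is Zone.DECISION and labels[i] in (
            Zone.ARM_LEFT,
            Zone.ARM_RIGHT,
        ):
            return labels[i], i
    return None
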