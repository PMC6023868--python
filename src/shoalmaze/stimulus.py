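"""Virtual leader/distractor silhouette simulator.

Silhouettes are projected into the circular decision zone of the maze.  A
fraction ``coherency`` of them are *leaders* that move ballistically toward
a target arm; the rest are *distractors* performing a correlated random
walk whose per-step turn angles follow a wrapped Cauchy distribution with a
circular standard deviation of 30°.  Leaders move at ``delta_v`` times the
baseline speed (1 body length per second, 3.5 cm/s).

Boundary conditions are periodic in density rather than in space: a
silhouette that leaves the zone fades out at a rate proportional to its
speed and is then re-placed uniformly at random inside the zone in the same
role, so both the silhouette count and the leader/distractor ratio are
constant at every frame.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .maze import MazeGeometry, Zone

__all__ = [
    "Role",
    "StimulusConfig",
    "Silhouette",
    "wrapped_cauchy_concentration",
    "sample_turn_angles",
    "init_silhouettes",
    "step_distractor",
    "step_leader",
    "apply_boundary",
    "simulate_stimuli",
]


class Role(enum.Enum):
    LEADER = "LEADER"
    DISTRACTOR = "DISTRACTOR"


def wrapped_cauchy_concentration(sd_deg: float) -> float:
    """Concentration (= mean resultant length) ρ for a given circular SD.

    Uses the circular-statistics relation σ_c = sqrt(−2 ln ρ), i.e.
    ρ = exp(−σ_c²/2).  For σ_c = 30° this gives ρ ≈ 0.8719.
    """
    sd = math.radians(sd_deg)
    return math.exp(-(sd**2) / 2.0)


def sample_turn_angles(rho: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw wrapped-Cauchy(0, ρ) turn angles in (−π, π] by inverse CDF."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    if rho >= 1.0:
        return np.zeros(size)
    u = rng.uniform(0.0, 1.0, size)
    return 2.0 * np.arctan(((1.0 - rho) / (1.0 + rho)) * np.tan(np.pi * (u - 0.5)))


@dataclass(frozen=True)
class StimulusConfig:
    """All tunable parameters of the silhouette projection.

    ``coherency`` is the leader fraction (signal/noise ratio of the visual
    cue); ``delta_v`` the leader:distractor speed ratio.  With
    ``null_fast`` set (the default), the no-leader condition C=0 renders
    every silhouette at delta_v × baseline speed, matching how the speed
    treatment is applied in the null cells.
    """

    n_silhouettes: int = 60
    coherency: float = 0.67
    delta_v: float = 10.0
    baseline_speed: float = 3.5  # cm/s == 1 body length / s
    body_length: float = 3.5  # cm
    fps: float = 60.0
    turn_sd_deg: float = 30.0
    target_arm: Zone = Zone.ARM_LEFT
    null_fast: bool = True
    fade_seconds_at_baseline: float = 1.0
    leader_boundary_extension: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coherency <= 1.0:
            raise ValueError("coherency must be in [0, 1]")
        if self.delta_v < 1.0:
            raise ValueError("delta_v must be >= 1")
        if self.n_silhouettes < 0:
            raise ValueError("n_silhouettes must be >= 0")
        if self.fps <= 0 or self.baseline_speed <= 0 or self.body_length <= 0:
            raise ValueError("fps, baseline_speed and body_length must be > 0")
        if self.target_arm not in (Zone.ARM_LEFT, Zone.ARM_RIGHT):
            raise ValueError("target_arm must be ARM_LEFT or ARM_RIGHT")

    @property
    def n_leaders(self) -> int:
        return int(round(self.coherency * self.n_silhouettes))

    @property
    def n_distractors(self) -> int:
        return self.n_silhouettes - self.n_leaders

    @property
    def rho(self) -> float:
        return wrapped_cauchy_concentration(self.turn_sd_deg)

    @property
    def leader_speed(self) -> float:
        return self.delta_v * self.baseline_speed

    def distractor_speed(self) -> float:
        """Distractor (= baseline) speed; in the C=0 null cell with
        ``null_fast`` all silhouettes carry the treatment speed."""
        if self.null_fast and self.coherency == 0.0:
            return self.delta_v * self.baseline_speed
        return self.baseline_speed

    @property
    def dt(self) -> float:
        return 1.0 / self.fps


@dataclass
class Silhouette:
    role: Role
    position: np.ndarray  # (2,) cm
    heading: float  # radians
    speed: float  # cm/s
    opacity: float = 1.0


def _uniform_in_disc(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
    th = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _aim(position: np.ndarray, target: np.ndarray, fallback: float) -> float:
    d = target - position
    if np.allclose(d, 0.0):
        return fallback
    return math.atan2(d[1], d[0])


def init_silhouettes(
    cfg: StimulusConfig, geom: MazeGeometry, rng: np.random.Generator
) -> list[Silhouette]:
    """Place silhouettes uniformly at random inside the decision zone.

    Leaders are aimed at the target-arm entrance; distractor headings are
    uniform on the circle.  All start fully opaque.
    """
    pos = _uniform_in_disc(cfg.n_silhouettes, geom.zone_radius, rng)
    entrance = geom.arm_entrance(cfg.target_arm)
    out: list[Silhouette] = []
    for i in range(cfg.n_silhouettes):
        if i < cfg.n_leaders:
            heading = _aim(pos[i], entrance, 0.0)
            out.append(Silhouette(Role.LEADER, pos[i], heading, cfg.leader_speed))
        else:
            heading = rng.uniform(-np.pi, np.pi)
            out.append(
                Silhouette(Role.DISTRACTOR, pos[i], heading, cfg.distractor_speed())
            )
    return out


def step_distractor(
    s: Silhouette, cfg: StimulusConfig, dt: float, rng: np.random.Generator
) -> Silhouette:
    """Advance a distractor one step of its correlated random walk."""
    if s.role is not Role.DISTRACTOR:
        raise ValueError("step_distractor applied to a non-distractor")
    delta = float(sample_turn_angles(cfg.rho, 1, rng)[0])
    heading = s.heading + delta
    pos = s.position + s.speed * dt * np.array([math.cos(heading), math.sin(heading)])
    return replace(s, position=pos, heading=heading)


def step_leader(
    s: Silhouette, cfg: StimulusConfig, geom: MazeGeometry, dt: float
) -> Silhouette:
    """Advance a leader ballistically toward the target-arm entrance.

    Once past the zone boundary the leader retains its last heading (it is
    fading out) instead of turning back toward the entrance.
    """
    if s.role is not Role.LEADER:
        raise ValueError("step_leader applied to a non-leader")
    if float(s.position @ s.position) <= geom.zone_radius**2:
        heading = _aim(s.position, geom.arm_entrance(cfg.target_arm), s.heading)
    else:
        heading = s.heading
    pos = s.position + s.speed * dt * np.array([math.cos(heading), math.sin(heading)])
    return replace(s, position=pos, heading=heading)


def _inside_visible_region(
    pos: np.ndarray, is_leader: np.ndarray, cfg: StimulusConfig, geom: MazeGeometry
) -> np.ndarray:
    """Visibility region per silhouette (vectorised).

    Distractors: the decision-zone disc.  Leaders: the disc extended back
    toward the holding arm by ``leader_boundary_extension`` (a capsule),
    used in the group-size experiment so leaders do not all vanish at the
    arm entrance at once.
    """
    r2 = geom.zone_radius**2
    inside = np.einsum("ij,ij->i", pos, pos) <= r2
    ext = cfg.leader_boundary_extension
    if ext > 0.0:
        axis = geom.holding_axis
        along = np.clip(pos @ axis, 0.0, ext)
        closest = along[:, None] * axis[None, :]
        d = pos - closest
        in_capsule = np.einsum("ij,ij->i", d, d) <= r2
        inside = np.where(is_leader, inside | in_capsule, inside)
    return inside


def apply_boundary(
    s: Silhouette, cfg: StimulusConfig, geom: MazeGeometry, rng: np.random.Generator
) -> Silhouette:
    """Fade a silhouette that has left its visible region; respawn when gone.

    Opacity drops by (speed / baseline_speed) × dt / fade_seconds each step,
    so a baseline-speed silhouette fades in ``fade_seconds_at_baseline`` and
    a 10× leader ten times faster.  A fully faded silhouette reappears
    uniformly at random inside the zone with opacity 1, same role;
    distractors retain their heading, leaders re-aim at the target arm.
    """
    pos = s.position[None, :]
    is_leader = np.array([s.role is Role.LEADER])
    if _inside_visible_region(pos, is_leader, cfg, geom)[0]:
        return s if s.opacity == 1.0 else replace(s, opacity=1.0)
    decay = (s.speed / cfg.baseline_speed) * cfg.dt / cfg.fade_seconds_at_baseline
    opacity = s.opacity - decay
    if opacity > 0.0:
        return replace(s, opacity=opacity)
    new_pos = _uniform_in_disc(1, geom.zone_radius, rng)[0]
    if s.role is Role.LEADER:
        heading = _aim(new_pos, geom.arm_entrance(cfg.target_arm), s.heading)
    else:
        heading = s.heading
    return replace(s, position=new_pos, heading=heading, opacity=1.0)


def simulate_stimuli(
    cfg: StimulusConfig, geom: MazeGeometry, duration: float
) -> pd.DataFrame:
    """Run the projection for ``duration`` seconds at cfg.fps.

    Returns a tidy frame stream with columns
    (frame, id, role, x, y, heading, opacity); frame 0 is the initial
    placement and each later frame advances the simulation by 1/fps s.
    Deterministic given ``cfg.seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(duration * cfg.fps))
    n = cfg.n_silhouettes
    dt = cfg.dt

    pos = _uniform_in_disc(n, geom.zone_radius, rng)
    is_leader = np.arange(n) < cfg.n_leaders
    entrance = geom.arm_entrance(cfg.target_arm)
    heading = rng.uniform(-np.pi, np.pi, n)
    d = entrance[None, :] - pos
    heading[is_leader] = np.arctan2(d[is_leader, 1], d[is_leader, 0])
    speed = np.where(is_leader, cfg.leader_speed, cfg.distractor_speed())
    opacity = np.ones(n)

    frames_pos = np.empty((n_frames, n, 2))
    frames_heading = np.empty((n_frames, n))
    frames_opacity = np.empty((n_frames, n))
    frames_pos[0], frames_heading[0], frames_opacity[0] = pos, heading, opacity

    fade = (speed / cfg.baseline_speed) * dt / cfg.fade_seconds_at_baseline
    for f in range(1, n_frames):
        # distractor CRW turns
        n_dis = int((~is_leader).sum())
        if n_dis:
            heading[~is_leader] += sample_turn_angles(cfg.rho, n_dis, rng)
        # leaders still inside aim at the entrance; fading ones hold course
        in_zone = np.einsum("ij,ij->i", pos, pos) <= geom.zone_radius**2
        aim_mask = is_leader & in_zone
        if aim_mask.any():
            d = entrance[None, :] - pos[aim_mask]
            heading[aim_mask] = np.arctan2(d[:, 1], d[:, 0])
        pos = pos + (speed * dt)[:, None] * np.column_stack(
            [np.cos(heading), np.sin(heading)]
        )
        visible = _inside_visible_region(pos, is_leader, cfg, geom)
        opacity = np.where(visible, 1.0, opacity - fade)
        gone = opacity <= 0.0
        if gone.any():
            k = int(gone.sum())
            pos[gone] = _uniform_in_disc(k, geom.zone_radius, rng)
            lead_gone = gone & is_leader
            if lead_gone.any():
                d = entrance[None, :] - pos[lead_gone]
                heading[lead_gone] = np.arctan2(d[:, 1], d[:, 0])
            opacity[gone] = 1.0
        frames_pos[f], frames_heading[f], frames_opacity[f] = pos, heading, opacity

    ids = np.tile(np.arange(n), n_frames)
    roles = np.where(is_leader, Role.LEADER.value, Role.DISTRACTOR.value)
    return pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), n),
            "id": ids,
            "role": np.tile(roles, n_frames),
            "x": frames_pos[:, :, 0].ravel(),
            "y": frames_pos[:, :, 1].ravel(),
            "heading": frames_heading.ravel(),
            "opacity": frames_opacity.ravel(),
        }
    )
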