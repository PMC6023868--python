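"""Generative model of fish departures, arm choices and trajectories.

This module is the synthetic stand-in for live-animal recordings.  It is
not a mechanistic model of zebrafish locomotion; it is the minimal
generative structure whose output carries the statistical signatures the
analysis pipeline is built to detect:

* a social-hazard departure process — each fish leaves the holding area
  with hazard ``latency_rate × (1 + social_hazard_boost × n_departed)``, so
  the subject's median time to act decays approximately as a power law of
  shoal size;
* a cue-plus-social choice mixture — the probability of following the
  virtual leaders combines a visual-cue weight (set by the follow
  probabilities per relative speed Δv) with a logistic social-feedback term
  ``1/(1 + exp(−a(N_c − b)))`` in the signed tally N_c of earlier-deciding
  companions (correct minus incorrect);
* a speed–accuracy trade-off — decision-zone transit times are drawn from
  gamma distributions whose means differ by correctness.

Choices are committed at the arm-crossing moment.  For solitary fish the
transit time is drawn conditioned on correctness (the full trade-off, which
is where the assay measures it).  In groups the crossing schedule is drawn
first — transit times from the correctness-marginal mixture — and each
fish's correctness is then drawn in crossing order, conditioned on the
signed tally N_c of fish that crossed strictly before it.  This keeps
P(correct | N_c) exactly logistic under the ledger's own definition of N_c
(no feedback from a fish's outcome into its own crossing time), while a
time–accuracy correlation still emerges in groups through social drift:
later crossers face larger tallies.  That correlation weakens as shoals
grow, consistent with the assay's observation that the individual
trade-off is obscured in larger groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinematics import DecisionRecord, Track, assign_decision_order
from .maze import MazeGeometry, Zone

__all__ = [
    "BehaviorParams",
    "TrialDesign",
    "Trial",
    "TrialDataset",
    "ChoiceContext",
    "choice_probability",
    "sample_choice",
    "sample_action_times",
    "simulate_decisions",
    "simulate_trial",
    "generate_dataset",
]


@dataclass(frozen=True)
class BehaviorParams:
    """All tunable parameters of the generative fish.

    Follow probabilities and the logistic coefficients default to the
    observed values of the assay they emulate: solitary fish follow the
    fast leaders with probability 0.85 and the matched-speed leaders with
    0.44; the social-feedback logistic has slope a = 0.52 and offset
    b = 0.07; transit times average 2.6 s (correct) vs 1.3 s (incorrect).
    The hazard boost of 15 per departed neighbour puts the power-law
    exponent of median time-to-act near −0.9 over shoals of 1–15.
    """

    p_follow_fast: float = 0.85
    p_follow_slow: float = 0.44
    p_program_match_null: float = 0.25
    social_a: float = 0.52
    social_b: float = 0.07
    latency_rate: float = 0.05  # 1/s
    social_hazard_boost: float = 15.0
    subject_rate_multiplier: float = 1.0
    td_correct_mean: float = 2.6  # s
    td_correct_sd: float = 2.0
    td_incorrect_mean: float = 1.3  # s
    td_incorrect_sd: float = 0.8
    swim_speed_mean: float = 1.0  # FL/s, holding-to-zone approach speed
    turn_sd_deg: float = 30.0
    body_length: float = 3.5  # cm
    trial_duration_s: float = 120.0
    holding_offset_cm: float = 3.0

    def __post_init__(self) -> None:
        for name in ("p_follow_fast", "p_follow_slow", "p_program_match_null"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        for name in (
            "latency_rate",
            "td_correct_mean",
            "td_correct_sd",
            "td_incorrect_mean",
            "td_incorrect_sd",
            "swim_speed_mean",
            "body_length",
            "trial_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.social_hazard_boost < 0:
            raise ValueError("social_hazard_boost must be >= 0")

    @property
    def travel_time_s(self) -> float:
        """Holding position to decision-zone entry at the approach speed."""
        return self.holding_offset_cm / (self.swim_speed_mean * self.body_length)


@dataclass(frozen=True)
class TrialDesign:
    trial_id: str
    experiment: int
    subject_id: str
    coherency: float
    delta_v: float
    n_fish: int
    target_arm: Zone

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        if self.coherency > 0 and self.target_arm not in (
            Zone.ARM_LEFT,
            Zone.ARM_RIGHT,
        ):
            raise ValueError("C > 0 requires a target arm")


@dataclass
class Trial:
    design: TrialDesign
    decisions: list[DecisionRecord]
    tracks: list[Track] = field(default_factory=list)
    gate_time: float = 0.0

    @property
    def subject_decision(self) -> DecisionRecord:
        return self.decisions[0]


@dataclass
class TrialDataset:
    """A factorial collection of trials with their design labels."""

    experiment: int
    trials: list[Trial]

    def decisions(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            d = tr.design
            for i, r in enumerate(tr.decisions):
                rows.append(
                    {
                        "trial": d.trial_id,
                        "experiment": d.experiment,
                        "subject": d.subject_id,
                        "fish": r.fish_id,
                        "is_subject": i == 0,
                        "coherency": d.coherency,
                        "delta_v": d.delta_v,
                        "n_fish": d.n_fish,
                        "target_arm": d.target_arm.value,
                        "arm": r.chosen_arm.value if r.chosen_arm else "",
                        "correct": np.nan if r.correct is None else float(r.correct),
                        "t_a": np.nan if r.t_a is None else r.t_a,
                        "t_d": np.nan if r.t_d is None else r.t_d,
                        "order": 0 if r.decision_order is None else r.decision_order,
                    }
                )
        return pd.DataFrame(rows)

    def subject_decisions(self) -> pd.DataFrame:
        df = self.decisions()
        return df[df["is_subject"]].reset_index(drop=True)


@dataclass(frozen=True)
class ChoiceContext:
    coherency: float
    delta_v: float
    n_c: int
    target_arm: Zone


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def choice_probability(
    coherency: float, delta_v: float, n_c: int, params: BehaviorParams
) -> float:
    """P(correct | C, Δv, N_c) under the cue-plus-social mixture.

    social = 1/(1+exp(−a(N_c − b))).  For C > 0,
    P = clip(w + (1 − w)·social) with the cue weight w solved so a solitary
    fish (N_c = 0) follows at exactly p_follow_fast (Δv > 1) or
    p_follow_slow (Δv = 1).  At C = 0 there is no visual cue; "correct"
    means matching the program's random arm designation, so the social term
    is scaled by 2·p_program_match_null, giving the 25 % two-independent-
    choices chance level when social feedback is flat (a = 0).
    """
    a, b = params.social_a, params.social_b
    social = _logistic(a * (n_c - b))
    if coherency == 0.0:
        return float(np.clip(2.0 * params.p_program_match_null * social, 0.0, 1.0))
    p_follow = params.p_follow_fast if delta_v > 1.0 else params.p_follow_slow
    s0 = _logistic(-a * b)  # social term at N_c = 0
    w = (p_follow - s0) / (1.0 - s0)
    return float(np.clip(w + (1.0 - w) * social, 0.0, 1.0))


def sample_choice(
    ctx: ChoiceContext, params: BehaviorParams, rng: np.random.Generator
) -> Zone:
    """Draw an arm choice for one fish given its decision-moment context."""
    p = choice_probability(ctx.coherency, ctx.delta_v, ctx.n_c, params)
    correct = rng.uniform() < p
    other = Zone.ARM_RIGHT if ctx.target_arm is Zone.ARM_LEFT else Zone.ARM_LEFT
    return ctx.target_arm if correct else other


def sample_action_times(
    n_fish: int, params: BehaviorParams, rng: np.random.Generator
) -> np.ndarray:
    """Departure times (s) for every fish in a trial; index 0 is the subject.

    Each remaining fish departs with hazard
    base_rate × (1 + social_hazard_boost × n_already_departed); the
    subject's base rate is latency_rate × subject_rate_multiplier,
    companions' is latency_rate.  The subject's time to act is its own
    departure time.  With boost 0 the times are i.i.d. exponentials.
    """
    if n_fish < 1:
        raise ValueError("n_fish must be >= 1")
    base = np.full(n_fish, params.latency_rate)
    base[0] *= params.subject_rate_multiplier
    times = np.empty(n_fish)
    remaining = np.arange(n_fish)
    t = 0.0
    for k in range(n_fish):
        rates = base[remaining] * (1.0 + params.social_hazard_boost * k)
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        pick = rng.choice(len(remaining), p=rates / total)
        times[remaining[pick]] = t
        remaining = np.delete(remaining, pick)
    return times


def _gamma_transit(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size)


def simulate_decisions(
    design: TrialDesign, params: BehaviorParams, rng: np.random.Generator
) -> tuple[list[DecisionRecord], dict]:
    """Simulate one trial's departures and arm choices without trajectories.

    Returns the per-fish decision records (subject first) and a schedule
    dict with the underlying departure / zone-entry / arm-crossing times
    used by the trajectory builder.

    Solitary trials: the choice is drawn at N_c = 0 and the transit time is
    then drawn conditioned on correctness (speed–accuracy trade-off).
    Group trials: the crossing schedule is drawn first (transit times from
    the correctness-marginal gamma mixture), then fish commit in crossing
    order, each with P(correct) evaluated at the signed tally of the fish
    that crossed strictly before it — the same tally the social ledger
    reconstructs.  Ties in crossing times are broken by fish id.
    """
    n = design.n_fish
    dep = sample_action_times(n, params, rng)
    entry = dep + params.travel_time_s
    decided = dep <= params.trial_duration_s
    fish_ids = [design.subject_id] + [f"c{j:02d}" for j in range(1, n)]

    correct = np.zeros(n, dtype=bool)
    if n == 1:
        p0 = choice_probability(design.coherency, design.delta_v, 0, params)
        correct[0] = rng.uniform() < p0
        if correct[0]:
            td = _gamma_transit(params.td_correct_mean, params.td_correct_sd, 1, rng)
        else:
            td = _gamma_transit(
                params.td_incorrect_mean, params.td_incorrect_sd, 1, rng
            )
        cross = np.where(decided, entry + td, np.inf)
    else:
        pi = choice_probability(design.coherency, design.delta_v, 0, params)
        branch = rng.uniform(size=n) < pi
        td = np.where(
            branch,
            _gamma_transit(params.td_correct_mean, params.td_correct_sd, n, rng),
            _gamma_transit(params.td_incorrect_mean, params.td_incorrect_sd, n, rng),
        )
        cross = np.where(decided, entry + td, np.inf)
        u = rng.uniform(size=n)
        order = sorted(
            (i for i in range(n) if decided[i]),
            key=lambda i: (cross[i], fish_ids[i]),
        )
        tally = 0
        for i in order:
            p = choice_probability(design.coherency, design.delta_v, tally, params)
            correct[i] = u[i] < p
            tally += 1 if correct[i] else -1
    other = (
        Zone.ARM_RIGHT if design.target_arm is Zone.ARM_LEFT else Zone.ARM_LEFT
    )
    records = []
    for i in range(n):
        if not decided[i]:
            records.append(DecisionRecord(fish_id=fish_ids[i]))
            continue
        records.append(
            DecisionRecord(
                fish_id=fish_ids[i],
                chosen_arm=design.target_arm if correct[i] else other,
                correct=bool(correct[i]),
                t_a=float(cross[i]),
                t_d=float(cross[i] - entry[i]),
            )
        )
    assign_decision_order(records)
    schedule = {"departure": dep, "entry": entry, "cross": cross, "decided": decided}
    return records, schedule


def _build_track(
    fish_id: str,
    departure: float,
    entry: float,
    cross: float,
    decided: bool,
    arm: Zone | None,
    trial_end: float,
    geom: MazeGeometry,
    params: BehaviorParams,
    rate: float,
) -> Track:
    """Piecewise trajectory: holding → approach → zone meander → arm.

    Segment boundaries are snapped to the frame grid so that decision
    extraction recovers the scheduled T_A and T_D up to one frame.  The
    in-zone path follows the entry→arm chord with a tapered sinusoidal
    meander; its traversal speed is implied by the drawn transit time.
    """
    r = geom.zone_radius
    hold = geom.holding_point(params.holding_offset_cm)
    end_f = int(round(trial_end * rate))
    if not decided:
        t = np.arange(end_f + 1) / rate
        xy = np.tile(hold, (len(t), 1))
        return Track(fish_id, t, xy[:, 0], xy[:, 1], rate, params.body_length)

    dep_f = int(round(departure * rate))
    entry_f = max(dep_f + 1, int(round(entry * rate)))
    cross_f = max(entry_f + 1, int(round(cross * rate)))
    end_f = max(end_f, cross_f + int(rate))  # at least 1 s inside the arm

    pre_entry = geom.holding_axis * (r + 0.2)  # just outside the zone
    entry_inner = geom.holding_axis * (r - 0.5)
    axis = geom.arm_axis(arm)
    pre_exit = axis * (r - 0.5)
    first_in_arm = axis * (r + 1.0)
    perp = np.array([-axis[1], axis[0]])

    pos = np.empty((end_f + 1, 2))
    pos[: dep_f + 1] = hold
    for f in range(dep_f + 1, entry_f):
        s = (f - dep_f) / (entry_f - dep_f)
        pos[f] = hold + s * (pre_entry - hold)
    n_zone = cross_f - entry_f
    for f in range(entry_f, cross_f):
        s = (f - entry_f) / n_zone
        base = entry_inner + s * (pre_exit - entry_inner)
        wiggle = 2.0 * math.sin(2.0 * math.pi * 2.0 * s) * math.sin(math.pi * s)
        pos[f] = base + wiggle * perp
    pos[cross_f] = first_in_arm
    speed_cm = params.swim_speed_mean * params.body_length
    for f in range(cross_f + 1, end_f + 1):
        along = min(r + 1.0 + speed_cm * (f - cross_f) / rate, r + geom.arm_length - 2.0)
        pos[f] = axis * along
    t = np.arange(end_f + 1) / rate
    return Track(fish_id, t, pos[:, 0], pos[:, 1], rate, params.body_length)


def simulate_trial(
    design: TrialDesign,
    params: BehaviorParams,
    geom: MazeGeometry,
    rng: np.random.Generator,
    sampling_rate: float = 10.0,
    tracks: bool = True,
) -> Trial:
    """Simulate one trial: decisions plus (optionally) per-fish tracks.

    When tracks are built, the decision records are re-derived from the
    frame-aligned crossing times so that timestamps and trajectories agree
    exactly.
    """
    records, sched = simulate_decisions(design, params, rng)
    trial = Trial(design=design, decisions=records)
    if not tracks:
        return trial

    finite = sched["cross"][sched["decided"]]
    trial_end = (
        min(params.trial_duration_s, float(finite.max()) + 2.0)
        if finite.size
        else params.trial_duration_s
    )
    fish_tracks = []
    for i, rec in enumerate(records):
        fish_tracks.append(
            _build_track(
                rec.fish_id,
                float(sched["departure"][i]),
                float(sched["entry"][i]),
                float(sched["cross"][i]),
                bool(sched["decided"][i]),
                rec.chosen_arm,
                trial_end,
                geom,
                params,
                sampling_rate,
            )
        )
    # re-align timestamps to the frame grid via extraction from the tracks
    from .kinematics import extract_decision

    new_records = []
    for i, tr in enumerate(fish_tracks):
        r = extract_decision(tr, geom, gate_time=0.0, target_arm=design.target_arm)
        new_records.append(r)
    assign_decision_order(new_records)
    trial.decisions = new_records
    trial.tracks = fish_tracks
    return trial


def _experiment_designs(
    experiment: int,
    rng: np.random.Generator,
    n_subjects: int | None = None,
) -> list[TrialDesign]:
    if experiment == 1:
        n_subjects = n_subjects or 20
        cells = [(c, dv) for c in (0.0, 0.33, 0.67, 1.0) for dv in (1.0, 10.0)]
        designs = []
        for s in range(1, n_subjects + 1):
            for c, dv in cells:
                target = Zone.ARM_LEFT if rng.uniform() < 0.5 else Zone.ARM_RIGHT
                designs.append(
                    TrialDesign(
                        trial_id=f"e1_s{s:02d}_C{c:g}_dv{dv:g}",
                        experiment=1,
                        subject_id=f"s{s:02d}",
                        coherency=c,
                        delta_v=dv,
                        n_fish=1,
                        target_arm=target,
                    )
                )
        return designs
    if experiment == 2:
        n_subjects = n_subjects or 24
        cells = [(n, dv) for n in (1, 5, 10, 15) for dv in (1.0, 10.0)]
        designs = []
        for s in range(1, n_subjects + 1):
            for n, dv in cells:
                target = Zone.ARM_LEFT if rng.uniform() < 0.5 else Zone.ARM_RIGHT
                designs.append(
                    TrialDesign(
                        trial_id=f"e2_s{s:02d}_N{n}_dv{dv:g}",
                        experiment=2,
                        subject_id=f"s{s:02d}",
                        coherency=0.67,
                        delta_v=dv,
                        n_fish=n,
                        target_arm=target,
                    )
                )
        return designs
    raise ValueError("experiment must be 1 or 2")


def generate_dataset(
    experiment: int,
    params: BehaviorParams | None = None,
    seed: int = 0,
    geom: MazeGeometry | None = None,
    tracks: bool = False,
    sampling_rate: float = 10.0,
    n_subjects: int | None = None,
) -> TrialDataset:
    """Generate a full factorial dataset for one experiment.

    Experiment 1: solitary subjects crossed with coherency × Δv
    (20 × 4 × 2 = 160 trials).  Experiment 2: subjects crossed with shoal
    size × Δv at fixed C = 0.67 (24 × 4 × 2 = 192 trials).  The target arm
    is randomised per trial.  Per-trial RNG streams are spawned from the
    master seed by trial index, so adding trials never perturbs existing
    ones.
    """
    params = params or BehaviorParams()
    geom = geom or MazeGeometry()
    design_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    designs = _experiment_designs(experiment, design_rng, n_subjects)
    trials = []
    for idx, design in enumerate(designs):
        trial_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1, idx))
        )
        trials.append(
            simulate_trial(
                design, params, geom, trial_rng, sampling_rate, tracks=tracks
            )
        )
    return TrialDataset(experiment=experiment, trials=trials)
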