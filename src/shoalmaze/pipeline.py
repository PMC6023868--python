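"""Orchestration: configuration, end-to-end runs, manifests, validation.

A run is fully determined by one master seed; per-trial RNG streams are
spawned from it by trial index, so configurations are reproducible
byte-for-byte and adding trials never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fish import BehaviorParams, generate_dataset
from .kinematics import tracks_to_csv
from .maze import MazeGeometry
from .stats import (
    build_social_ledger,
    exact_binomial_test,
    logistic_social_fit,
    pearson_r,
    powerlaw_fit,
    sat_comparison,
)

__all__ = ["RunConfig", "run_experiment", "validate_inputs"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    experiment: int = 1
    seed: int = 0
    out_dir: str = "run_out"
    params: BehaviorParams = field(default_factory=BehaviorParams)
    geometry: MazeGeometry = field(default_factory=MazeGeometry)
    tracks: bool = False
    sampling_rate: float = 10.0
    include_censored: bool = False
    merge_singletons: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "params" in d and isinstance(d["params"], dict):
            d["params"] = BehaviorParams(**d["params"])
        if "geometry" in d and isinstance(d["geometry"], dict):
            d["geometry"] = MazeGeometry(**d["geometry"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _analyze(decisions: pd.DataFrame, config: RunConfig) -> dict:
    """The standard analysis battery for one generated experiment."""
    subj = decisions[decisions["is_subject"]].copy()
    decided = subj[np.isfinite(subj["t_a"])]
    out: dict = {"n_trials": int(len(subj)), "n_decided": int(len(decided))}

    # arm bias and accuracy binomials
    n_left = int((decided["arm"] == "ARM_LEFT").sum())
    n_dec = int(len(decided))
    if n_dec:
        bt = exact_binomial_test(n_left, n_dec, 0.5)
        out["arm_bias"] = {"n_left": n_left, "n": n_dec, "p_value": bt.p_value}
        k = int(decided["correct"].sum())
        bt = exact_binomial_test(k, n_dec, 0.5)
        out["accuracy"] = {
            "n_correct": k,
            "n": n_dec,
            "p_hat": bt.p_hat,
            "p_value": bt.p_value,
        }

    # speed-accuracy trade-off among fast-cue deciders
    fast = decided[decided["delta_v"] > 1]
    td_c = fast[fast["correct"] == 1]["t_d"].to_numpy()
    td_i = fast[fast["correct"] == 0]["t_d"].to_numpy()
    if td_c.size and td_i.size:
        r = sat_comparison(td_c, td_i)
        out["sat"] = {
            "median_td_correct": float(np.median(td_c)),
            "median_td_incorrect": float(np.median(td_i)),
            "W": r.statistic,
            "p_value": r.p_value,
        }

    if config.experiment == 2:
        ledger = build_social_ledger(decisions)
        out["social"] = {}
        for dv, g in ledger.rows.groupby("delta_v"):
            try:
                fit = logistic_social_fit(g, merge_singletons=config.merge_singletons)
                out["social"][f"dv{dv:g}"] = {
                    "a": fit.a,
                    "b": fit.b,
                    "se_a": fit.se_a,
                    "t_a": fit.t_a,
                    "n": fit.n,
                    "converged": fit.converged,
                    "n_merged": fit.n_merged,
                }
            except ValueError as exc:
                out["social"][f"dv{dv:g}"] = {"error": str(exc)}
        medians = [
            (n, float(np.median(g[np.isfinite(g["t_a"])]["t_a"])))
            for n, g in subj.groupby("n_fish")
        ]
        medians = [(n, m) for n, m in medians if np.isfinite(m) and m > 0]
        if len(medians) >= 3:
            pl = powerlaw_fit(medians)
            out["powerlaw"] = {
                "exponent": pl.exponent,
                "r_squared": pl.r_squared,
                "medians": {f"N{int(n)}": m for n, m in medians},
            }
        out["td_accuracy_correlation"] = {}
        for n, g in decided.groupby("n_fish"):
            g = g[np.isfinite(g["t_d"])]
            if len(g) >= 3 and g["correct"].nunique() > 1 and g["t_d"].nunique() > 1:
                out["td_accuracy_correlation"][f"N{int(n)}"] = pearson_r(
                    g["t_d"], g["correct"]
                )
    return out


def run_experiment(config: RunConfig) -> dict:
    """Generate, analyze and persist one experiment run.

    Writes decisions.csv, analysis.json, config.yaml and manifest.json
    (plus tracks.csv when trajectories are enabled) into ``out_dir`` and
    returns the analysis dict.  Identical configurations produce
    byte-identical outputs.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    probe = os.path.join(config.out_dir, ".write_probe")
    with open(probe, "w") as fh:
        fh.write("ok")
    os.remove(probe)

    dataset = generate_dataset(
        config.experiment,
        config.params,
        seed=config.seed,
        geom=config.geometry,
        tracks=config.tracks,
        sampling_rate=config.sampling_rate,
    )
    decisions = dataset.decisions()
    dec_path = os.path.join(config.out_dir, "decisions.csv")
    decisions.to_csv(dec_path, index=False, float_format="%.6f")

    files = {"decisions.csv": dec_path}
    if config.tracks:
        tracks = {t.design.trial_id: t.tracks for t in dataset.trials}
        trk_path = os.path.join(config.out_dir, "tracks.csv")
        tracks_to_csv(tracks, trk_path)
        files["tracks.csv"] = trk_path

    analysis = _analyze(decisions, config)
    ana_path = os.path.join(config.out_dir, "analysis.json")
    with open(ana_path, "w") as fh:
        json.dump(analysis, fh, indent=2, sort_keys=True, default=float)
    files["analysis.json"] = ana_path

    cfg_path = os.path.join(config.out_dir, "config.yaml")
    config.to_yaml(cfg_path)
    files["config.yaml"] = cfg_path

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "experiment": config.experiment,
        "config": config.to_dict(),
        "checksums": {name: _sha256(p) for name, p in sorted(files.items())},
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return analysis


def validate_inputs(path: str) -> list[dict]:
    """Check a trajectory CSV for structural problems.

    Returns a machine-readable issue list; an empty list means the file is
    usable as-is.  Severity "warning" issues (e.g. unsorted rows) are
    recoverable, "error" issues are not.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed CSV: {exc}") from exc
    issues: list[dict] = []
    required = {"trial", "fish", "frame", "t", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        issues.append(
            {"severity": "error", "issue": f"missing columns: {sorted(missing)}"}
        )
        return issues
    for (trial, fish), g in df.groupby(["trial", "fish"]):
        t = g["t"].to_numpy()
        if g["frame"].duplicated().any():
            issues.append(
                {
                    "severity": "error",
                    "issue": "duplicated frame index",
                    "trial": str(trial),
                    "fish": str(fish),
                }
            )
        elif not np.all(np.diff(t) > 0):
            if np.all(np.diff(np.sort(t)) > 0):
                issues.append(
                    {
                        "severity": "warning",
                        "issue": "rows not sorted by time (re-sortable)",
                        "trial": str(trial),
                        "fish": str(fish),
                    }
                )
            else:
                issues.append(
                    {
                        "severity": "error",
                        "issue": "non-monotone timestamps",
                        "trial": str(trial),
                        "fish": str(fish),
                    }
                )
    # unit plausibility: maze coordinates live within ~1 m of the origin
    if np.nanmax(np.abs(df[["x", "y"]].to_numpy())) > 500:
        issues.append(
            {
                "severity": "warning",
                "issue": "coordinates exceed 500 cm; are units really cm?",
            }
        )
    return issues
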