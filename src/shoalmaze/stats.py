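"""Decision statistics: binomial tests, speed–accuracy comparison, the
social-feedback logistic model, power-law latency scaling, and
fixed-effects accuracy regression.

Random-effects mixed models are deliberately not part of this module;
subject-level permutation p-values are offered as the robustness
substitute for repeated-measures designs (see ``accuracy_regression``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "BinomialResult",
    "RankSumResult",
    "SocialLedger",
    "LogisticFit",
    "PowerLawFit",
    "exact_binomial_test",
    "sat_comparison",
    "build_social_ledger",
    "logistic_social_fit",
    "powerlaw_fit",
    "accuracy_regression",
    "chi_square_2x2",
    "pearson_r",
    "median_time_to_act",
]


@dataclass(frozen=True)
class BinomialResult:
    k: int
    n: int
    p0: float
    p_hat: float
    p_value: float


def exact_binomial_test(k: int, n: int, p0: float = 0.5) -> BinomialResult:
    """Exact two-sided binomial test (small-likelihood method).

    The two-sided p-value sums P(X = j) over all j whose point probability
    does not exceed P(X = k) (up to a 1e-7 relative tolerance), the
    convention of mainstream statistical software.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    res = sps.binomtest(k, n, p0, alternative="two-sided")
    return BinomialResult(k=k, n=n, p0=p0, p_hat=k / n, p_value=float(res.pvalue))


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann–Whitney U of the first sample
    p_value: float
    n1: int
    n2: int
    tied: bool = False


def sat_comparison(
    td_first: Sequence[float], td_second: Sequence[float]
) -> RankSumResult:
    """Wilcoxon rank-sum comparison of two transit-time samples.

    The statistic is the Mann–Whitney U of the first sample: the number of
    (x, y) pairs with x > y plus half the ties.  The p-value is exact for
    combined n ≤ 20 (no ties), otherwise a tie-corrected normal
    approximation.  Identical samples return p = 1 with a tie flag.
    """
    x = np.asarray(td_first, dtype=float)
    y = np.asarray(td_second, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    all_same = np.unique(np.concatenate([x, y])).size == 1
    if all_same:
        return RankSumResult(len(x) * len(y) / 2.0, 1.0, len(x), len(y), tied=True)
    has_ties = np.unique(np.concatenate([x, y])).size < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(x),
        n2=len(y),
        tied=has_ties,
    )


@dataclass
class SocialLedger:
    """Per-subject-decision social context rows.

    Each row holds the signed tally N_c — companions that crossed strictly
    before the subject, correct minus incorrect — together with the
    subject's own outcome and the trial's design labels.
    """

    rows: pd.DataFrame  # columns: trial, n_c, subject_correct, delta_v, n_fish
    n_excluded: int = 0  # subjects without a decision


def build_social_ledger(decisions: pd.DataFrame) -> SocialLedger:
    """Tabulate N_c for every subject decision in a tidy decisions table.

    ``decisions`` needs columns trial, is_subject, correct, t_a, delta_v,
    n_fish (the layout produced by TrialDataset.decisions()).  Companions
    with no decision contribute 0; subjects with no decision are excluded
    and counted.
    """
    rows = []
    n_excluded = 0
    for trial_id, g in decisions.groupby("trial", sort=True):
        subj = g[g["is_subject"]]
        if len(subj) != 1:
            raise ValueError(f"trial {trial_id} must have exactly one subject")
        subj = subj.iloc[0]
        if not np.isfinite(subj["t_a"]):
            n_excluded += 1
            continue
        comp = g[~g["is_subject"]]
        ahead = comp[np.isfinite(comp["t_a"]) & (comp["t_a"] < subj["t_a"])]
        n_c = int(ahead["correct"].sum() - (1 - ahead["correct"]).sum())
        rows.append(
            {
                "trial": trial_id,
                "n_c": n_c,
                "subject_correct": bool(subj["correct"]),
                "delta_v": subj["delta_v"],
                "n_fish": subj["n_fish"],
            }
        )
    return SocialLedger(rows=pd.DataFrame(rows), n_excluded=n_excluded)


@dataclass(frozen=True)
class LogisticFit:
    a: float
    b: float
    se_a: float
    se_b: float
    t_a: float  # slope test statistic, a / se_a
    log_likelihood: float
    n: int
    converged: bool
    n_merged: int = 0  # rows moved by singleton-level merging


def _merge_singleton_levels(n_c: np.ndarray) -> tuple[np.ndarray, int]:
    """Merge N_c levels with a single observation into their nearest
    populated level (the package's alternative to dropping such rows)."""
    vals, counts = np.unique(n_c, return_counts=True)
    keep = vals[counts > 1]
    if keep.size == 0:
        return n_c, 0
    out = n_c.astype(float).copy()
    moved = 0
    for v in vals[counts == 1]:
        nearest = keep[np.argmin(np.abs(keep - v))]
        out[n_c == v] = nearest
        moved += 1
    return out, moved


def logistic_social_fit(
    ledger_rows: pd.DataFrame, merge_singletons: bool = False
) -> LogisticFit:
    """Maximum-likelihood fit of P(correct | N_c) = 1/(1+exp(−a(N_c − b))).

    Fitted via the reparameterisation logit p = β0 + β1·N_c with a = β1,
    b = −β0/β1; standard errors come from the observed information (delta
    method for b).  Complete separation is reported as non-convergence
    rather than silent estimates.  Rows should be one Δv level of a social
    ledger.
    """
    n_c = ledger_rows["n_c"].to_numpy(dtype=float)
    y = ledger_rows["subject_correct"].to_numpy(dtype=float)
    n_merged = 0
    if merge_singletons:
        n_c, n_merged = _merge_singleton_levels(n_c)
    if np.unique(n_c).size < 2 or np.unique(y).size < 2:
        raise ValueError("need >=2 distinct N_c levels and both outcomes")
    X = sm.add_constant(n_c)
    try:
        fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        return LogisticFit(
            math.nan, math.nan, math.nan, math.nan, math.nan, math.nan,
            len(y), False, n_merged,
        )
    beta0, beta1 = fit.params
    cov = fit.cov_params()
    if not np.all(np.isfinite(cov)) or abs(beta1) > 50 or not converged:
        return LogisticFit(
            float(beta1), math.nan, math.nan, math.nan, math.nan,
            float(fit.llf), len(y), False, n_merged,
        )
    a = float(beta1)
    b = float(-beta0 / beta1)
    se_a = float(np.sqrt(cov[1, 1]))
    # delta method: b = -β0/β1; grad = (-1/β1, β0/β1²)
    g = np.array([-1.0 / beta1, beta0 / beta1**2])
    se_b = float(np.sqrt(g @ cov @ g))
    return LogisticFit(
        a=a,
        b=b,
        se_a=se_a,
        se_b=se_b,
        t_a=a / se_a,
        log_likelihood=float(fit.llf),
        n=len(y),
        converged=True,
        n_merged=n_merged,
    )


@dataclass(frozen=True)
class PowerLawFit:
    exponent: float
    intercept: float  # log-scale intercept
    r_squared: float
    group_sizes: tuple
    medians: tuple


def powerlaw_fit(pairs: Sequence[tuple[float, float]]) -> PowerLawFit:
    """OLS fit of log(median) on log(N): median ≈ exp(intercept) · N^exponent."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 (N, median) pairs")
    n = np.array([p[0] for p in pairs], dtype=float)
    m = np.array([p[1] for p in pairs], dtype=float)
    if np.any(n <= 0) or np.any(m <= 0):
        raise ValueError("group sizes and medians must be positive")
    if np.unique(n).size < 3:
        raise ValueError("need at least 3 distinct group sizes")
    res = sps.linregress(np.log(n), np.log(m))
    return PowerLawFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        group_sizes=tuple(n),
        medians=tuple(m),
    )


def median_time_to_act(
    decisions: pd.DataFrame, include_censored: bool = False, censor_time: float = 120.0
) -> float:
    """Median subject T_A; non-deciders are excluded by default or entered
    at the trial-end censoring time when ``include_censored`` is set."""
    t = decisions["t_a"].to_numpy(dtype=float)
    if include_censored:
        t = np.where(np.isfinite(t), t, censor_time)
    else:
        t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no time-to-act values available")
    return float(np.median(t))


def accuracy_regression(
    decisions: pd.DataFrame,
    factors: Sequence[str],
    permutations: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed-effects logistic regression of subject correctness on design
    factors (any of coherency, delta_v, n_fish, n_c, t_d).

    Returns a coefficient table with Wald z statistics and, when
    ``permutations`` > 0, within-subject permutation p-values: outcomes are
    shuffled within each subject's block of trials, which preserves
    subject-level accuracy while breaking factor–outcome association —
    the substitute for a random subject intercept.
    """
    if not factors:
        raise ValueError("at least one factor required")
    df = decisions.copy()
    df = df[np.isfinite(df["correct"])]
    y = df["correct"].to_numpy(dtype=float)
    X = sm.add_constant(df[list(factors)].to_numpy(dtype=float))
    names = ["const"] + list(factors)
    fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    if not fit.mle_retvals.get("converged", True) or np.any(
        np.abs(fit.params) > 50
    ):
        raise RuntimeError("logistic regression did not converge (separation?)")
    table = pd.DataFrame(
        {
            "term": names,
            "coef": fit.params,
            "se": fit.bse,
            "z": fit.params / fit.bse,
            "p_wald": fit.pvalues,
        }
    )
    if permutations > 0:
        rng = np.random.default_rng(seed)
        subjects = df["subject"].to_numpy()
        obs = np.abs(fit.params)
        exceed = np.zeros(len(names))
        groups = [np.flatnonzero(subjects == s) for s in np.unique(subjects)]
        for _ in range(permutations):
            y_perm = y.copy()
            for idx in groups:
                y_perm[idx] = y[rng.permutation(idx)]
            try:
                pf = sm.Logit(y_perm, X).fit(disp=False, maxiter=100)
                exceed += np.abs(pf.params) >= obs
            except Exception:
                exceed += 1  # conservative on a failed refit
        table["p_perm"] = (exceed + 1) / (permutations + 1)
    return table


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2×2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    return float(sps.pearsonr(x, y).statistic)
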