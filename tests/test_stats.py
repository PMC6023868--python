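"""Decision statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from shoalmaze.fish import BehaviorParams, TrialDesign, simulate_decisions
from shoalmaze.maze import Zone
from shoalmaze.stats import (
    accuracy_regression,
    build_social_ledger,
    chi_square_2x2,
    exact_binomial_test,
    logistic_social_fit,
    median_time_to_act,
    pearson_r,
    powerlaw_fit,
    sat_comparison,
)


def brute_force_binomial_p(k, n, p0):
    """Enumerate all point probabilities; sum those <= P(X=k)·(1+1e-7)."""
    pmf = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] * (1 + 1e-7)))


class TestExactBinomial:
    def test_matches_enumeration_for_small_n(self):
        for n in range(1, 26):
            for p0 in (0.25, 0.5, 0.75):
                for k in range(n + 1):
                    got = exact_binomial_test(k, n, p0).p_value
                    assert got == pytest.approx(
                        brute_force_binomial_p(k, n, p0), abs=1e-10
                    ), (k, n, p0)

    def test_all_successes_small_n(self):
        assert exact_binomial_test(3, 3, 0.5).p_value == pytest.approx(0.25)

    def test_p_hat(self):
        r = exact_binomial_test(16, 40)
        assert r.p_hat == pytest.approx(0.40)

    @pytest.mark.parametrize("k,n,p0", [(1, 0, 0.5), (-1, 5, 0.5), (6, 5, 0.5), (2, 5, 0.0)])
    def test_invalid_inputs(self, k, n, p0):
        with pytest.raises(ValueError):
            exact_binomial_test(k, n, p0)


class TestSatComparison:
    def test_fully_separated_small_samples(self):
        """All y exceed x: U = 0 and the exact p enumerates C(6,3) splits."""
        r = sat_comparison([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        r = sat_comparison([2.0, 2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0 and r.tied

    def test_exchangeable_samples_not_significant(self, rng):
        x = rng.normal(0, 1, 50)
        r = sat_comparison(x, x.copy())
        assert r.p_value > 0.9

    def test_power_against_unit_shift(self, rng):
        rejections = 0
        for _ in range(25):
            x = rng.normal(1.0, 1.0, 200)
            y = rng.normal(0.0, 1.0, 200)
            rejections += sat_comparison(x, y).p_value < 0.001
        assert rejections == 25

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sat_comparison([], [1.0])


def ledger_frame(rows):
    return pd.DataFrame(rows)


def make_decisions_frame(trials):
    """trials: list of (subject_t_a, subject_correct, [(t_a, correct), ...])."""
    rows = []
    for i, (sta, sc, comps) in enumerate(trials):
        rows.append(
            {
                "trial": f"t{i:03d}",
                "is_subject": True,
                "correct": np.nan if sc is None else float(sc),
                "t_a": np.nan if sta is None else sta,
                "delta_v": 1.0,
                "n_fish": len(comps) + 1,
            }
        )
        for t_a, c in comps:
            rows.append(
                {
                    "trial": f"t{i:03d}",
                    "is_subject": False,
                    "correct": np.nan if c is None else float(c),
                    "t_a": np.nan if t_a is None else t_a,
                    "delta_v": 1.0,
                    "n_fish": len(comps) + 1,
                }
            )
    return pd.DataFrame(rows)


class TestSocialLedger:
    def test_subject_first_has_zero_tally(self):
        df = make_decisions_frame([(1.0, True, [(2.0, True), (3.0, False)])])
        led = build_social_ledger(df)
        assert led.rows.iloc[0]["n_c"] == 0

    def test_signed_tally(self):
        comps = [(0.5, True), (0.7, True), (0.9, False), (2.0, True)]
        df = make_decisions_frame([(1.0, True, comps)])
        led = build_social_ledger(df)
        assert led.rows.iloc[0]["n_c"] == 1  # 2 correct - 1 incorrect ahead

    def test_non_deciding_companions_contribute_zero(self):
        df = make_decisions_frame([(1.0, True, [(None, None), (0.5, False)])])
        led = build_social_ledger(df)
        assert led.rows.iloc[0]["n_c"] == -1

    def test_non_deciding_subject_excluded(self):
        df = make_decisions_frame([(None, None, [(0.5, True)])])
        led = build_social_ledger(df)
        assert len(led.rows) == 0 and led.n_excluded == 1

    def test_matches_brute_force_recount(self, rng):
        trials = []
        for _ in range(40):
            n_comp = int(rng.integers(0, 10))
            comps = [
                (float(rng.uniform(0, 20)), bool(rng.uniform() < 0.5))
                for _ in range(n_comp)
            ]
            trials.append((float(rng.uniform(0, 20)), True, comps))
        df = make_decisions_frame(trials)
        led = build_social_ledger(df).rows.set_index("trial")
        for i, (sta, _, comps) in enumerate(trials):
            expected = sum(1 if c else -1 for t, c in comps if t < sta)
            assert led.loc[f"t{i:03d}", "n_c"] == expected

    def test_companion_relabeling_leaves_tally_unchanged(self, rng):
        comps = [(0.2, True), (0.4, False), (0.6, True)]
        df = make_decisions_frame([(1.0, True, comps)])
        shuffled = make_decisions_frame([(1.0, True, comps[::-1])])
        a = build_social_ledger(df).rows.iloc[0]["n_c"]
        b = build_social_ledger(shuffled).rows.iloc[0]["n_c"]
        assert a == b


class TestLogisticSocialFit:
    def test_direct_generation_recovers_slope(self, rng):
        n_c = rng.integers(-8, 9, size=2000)
        p = 1.0 / (1.0 + np.exp(-0.5 * (n_c - 0.0)))
        y = rng.uniform(size=2000) < p
        fit = logistic_social_fit(
            pd.DataFrame({"n_c": n_c, "subject_correct": y})
        )
        assert fit.converged
        assert fit.a == pytest.approx(0.5, abs=0.1)
        assert abs(fit.b) < 0.5

    def test_null_slope_type_one_error(self):
        rejections = 0
        reps = 30
        for seed in range(reps):
            r = np.random.default_rng(seed)
            n_c = r.integers(-5, 6, size=400)
            y = r.uniform(size=400) < 0.6  # outcome independent of n_c
            fit = logistic_social_fit(pd.DataFrame({"n_c": n_c, "subject_correct": y}))
            rejections += abs(fit.t_a) > 1.96
        assert rejections <= 5  # ~5% nominal; allow binomial slack

    def test_complete_separation_flagged(self):
        df = pd.DataFrame(
            {"n_c": [-2, -1, 1, 2], "subject_correct": [False, False, True, True]}
        )
        fit = logistic_social_fit(df)
        assert not fit.converged

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            logistic_social_fit(
                pd.DataFrame({"n_c": [1, 1, 1], "subject_correct": [True, False, True]})
            )

    def test_singleton_level_merging_counts_rows(self):
        df = pd.DataFrame(
            {
                "n_c": [0, 0, 0, 0, 1, 1, 1, 1, 7, -6],
                "subject_correct": [True, False, True, False, True, True, False, True,
                                    True, False],
            }
        )
        fit = logistic_social_fit(df, merge_singletons=True)
        assert fit.n_merged == 2


class TestPowerLaw:
    def test_exact_inverse_law(self):
        pairs = [(n, 8.0 / n) for n in (1, 5, 10, 15)]
        fit = powerlaw_fit(pairs)
        assert fit.exponent == pytest.approx(-1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_medians(self):
        fit = powerlaw_fit([(1, 4.0), (5, 4.0), (10, 4.0)])
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self, rng):
        pairs = [(n, float(rng.uniform(1, 10))) for n in (1, 5, 10, 15)]
        a = powerlaw_fit(pairs)
        b = powerlaw_fit([(n, 3.7 * m) for n, m in pairs])
        assert b.exponent == pytest.approx(a.exponent, abs=1e-12)
        assert b.intercept == pytest.approx(a.intercept + math.log(3.7), abs=1e-10)
        assert b.r_squared == pytest.approx(a.r_squared, abs=1e-10)

    @pytest.mark.parametrize(
        "pairs",
        [[(1, 2.0), (5, 1.0)], [(1, 2.0), (5, 1.0), (10, -1.0)], [(1, 1.0)] * 3],
    )
    def test_invalid_inputs(self, pairs):
        with pytest.raises(ValueError):
            powerlaw_fit(pairs)


class TestChiSquare:
    def test_perfect_independence(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # margins all 30, expected 15 in each cell: 4 * 25/15 = 20/3
        stat, _ = chi_square_2x2([[20, 10], [10, 20]])
        assert stat == pytest.approx(20.0 / 3.0, abs=1e-9)

    def test_p_matches_independent_tail_formula(self):
        # 1 df chi-square survival: P(X > x) = erfc(sqrt(x/2))
        for table in ([[20, 10], [10, 20]], [[5, 9], [12, 7]], [[40, 2], [3, 50]]):
            stat, p = chi_square_2x2(table)
            assert p == pytest.approx(math.erfc(math.sqrt(stat / 2.0)), abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x) == pytest.approx(1.0)

    def test_orthogonalized_residuals(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 1, 200)
        xc = x - x.mean()
        resid = y - (xc @ (y - y.mean())) / (xc @ xc) * xc
        assert abs(pearson_r(x, resid)) < 1e-12

    def test_sampling_check_bivariate_normal(self, rng):
        n = 100_000
        x = rng.normal(0, 1, n)
        y = 0.3 * x + math.sqrt(1 - 0.09) * rng.normal(0, 1, n)
        assert pearson_r(x, y) == pytest.approx(0.30, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _regression_frame(rng, n_subj=20, trials_per=8, dv_effect=0.0):
    rows = []
    for s in range(n_subj):
        for t in range(trials_per):
            dv = 1.0 if t % 2 == 0 else 10.0
            logit = 0.1 + dv_effect * (dv == 10.0)
            p = 1 / (1 + math.exp(-logit))
            rows.append(
                {
                    "subject": f"s{s:02d}",
                    "delta_v": dv,
                    "correct": float(rng.uniform() < p),
                }
            )
    return pd.DataFrame(rows)


class TestAccuracyRegression:
    def test_null_effect_not_significant(self, rng):
        df = _regression_frame(rng, dv_effect=0.0)
        table = accuracy_regression(df, ["delta_v"], permutations=300, seed=1)
        row = table[table["term"] == "delta_v"].iloc[0]
        assert abs(row["z"]) < 3.0
        assert row["p_perm"] > 0.01

    def test_injected_effect_detected(self, rng):
        df = _regression_frame(rng, n_subj=40, trials_per=10, dv_effect=1.5)
        table = accuracy_regression(df, ["delta_v"], permutations=300, seed=1)
        row = table[table["term"] == "delta_v"].iloc[0]
        assert row["coef"] > 0 and row["p_wald"] < 0.01 and row["p_perm"] < 0.05

    def test_single_binary_factor_matches_closed_form_log_odds(self, rng):
        df = _regression_frame(rng, n_subj=50, trials_per=10, dv_effect=1.0)
        table = accuracy_regression(df, ["delta_v"])
        p1 = df[df["delta_v"] == 1.0]["correct"].mean()
        p10 = df[df["delta_v"] == 10.0]["correct"].mean()
        expected_slope = (math.log(p10 / (1 - p10)) - math.log(p1 / (1 - p1))) / 9.0
        got = table[table["term"] == "delta_v"].iloc[0]["coef"]
        assert got == pytest.approx(expected_slope, abs=1e-6)


class TestMedianTimeToAct:
    def test_censoring_modes(self):
        df = pd.DataFrame({"t_a": [1.0, 2.0, np.nan, np.nan]})
        assert median_time_to_act(df) == pytest.approx(1.5)
        assert median_time_to_act(df, include_censored=True, censor_time=100.0) == (
            pytest.approx(51.0)
        )


class TestEndToEndEffects:
    def test_delta_v_effect_and_no_coherency_effect_at_slow_speed(self):
        """Generated solitary data reproduce a strong relative-speed effect
        on accuracy and no coherency effect within the slow-cue cells."""
        params = BehaviorParams()
        rng = np.random.default_rng(31)
        rows = []
        for i in range(1200):
            c = float(rng.choice([0.33, 0.67, 1.0]))
            dv = float(rng.choice([1.0, 10.0]))
            d = TrialDesign(f"t{i}", 1, f"s{i % 20:02d}", c, dv, 1, Zone.ARM_LEFT)
            recs, _ = simulate_decisions(d, params, rng)
            if recs[0].decided:
                rows.append(
                    {
                        "subject": d.subject_id,
                        "coherency": c,
                        "delta_v": dv,
                        "correct": float(recs[0].correct),
                    }
                )
        df = pd.DataFrame(rows)
        table = accuracy_regression(df, ["delta_v"])
        assert table[table["term"] == "delta_v"].iloc[0]["p_wald"] < 1e-6
        slow = df[df["delta_v"] == 1.0]
        table_c = accuracy_regression(slow, ["coherency"])
        assert table_c[table_c["term"] == "coherency"].iloc[0]["p_wald"] > 0.01
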