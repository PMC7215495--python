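import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tailorrec.data_model import RatingEvent, TrialRecord
from tailorrec.trial_stats import (
    ContingencyTable2x2,
    chi_square_2x2,
    compare_daily_ratings,
    daily_group_means,
    dichotomize_impact,
    fit_logistic,
    mediation_analysis,
    odds_ratio_2x2,
    percentage,
    quit_table,
    trend_test_2xk,
)

#: the published follow-up cessation counts: 30/51 quitters vs 19/50
QUIT_TABLE = ContingencyTable2x2(30, 21, 19, 31)


class TestDailyRatings:
    def test_group_day_means_match_hand_arithmetic(self):
        roster = {"a1": "g1", "a2": "g1", "b1": "g2"}
        events = [
            RatingEvent("a1", "m1", 1, 4),
            RatingEvent("a2", "m2", 1, 5),
            RatingEvent("a1", "m3", 2, 3),
            RatingEvent("b1", "m1", 1, 2),
            RatingEvent("b1", "m4", 3, None),  # unrated send contributes nothing
        ]
        series = daily_group_means(events, roster, n_days=3)
        assert series["g1"].means[0] == pytest.approx(4.5)
        assert series["g1"].means[1] == pytest.approx(3.0)
        assert math.isnan(series["g1"].means[2])  # empty day is missing, not 0
        assert series["g2"].means[0] == pytest.approx(2.0)
        assert math.isnan(series["g2"].means[2])
        assert series["g2"].n_raters.tolist() == [1, 0, 0]

    def test_identical_series_compare_as_null(self):
        roster = {"a": "g1", "b": "g2"}
        events = []
        for d in range(1, 31):
            events.append(RatingEvent("a", f"x{d}", d, 4))
            events.append(RatingEvent("b", f"y{d}", d, 4))
        s = daily_group_means(events, roster)
        out = compare_daily_ratings(s["g1"], s["g2"])
        assert out["days_a_higher"] == 0
        assert out["t"] == pytest.approx(0.0)

    def test_uniform_offset_makes_every_day_higher(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(3.0, 4.0, 30)
        from tailorrec.trial_stats import DailyRatingSeries

        sa = DailyRatingSeries("g1", base + 0.2, np.full(30, 5))
        sb = DailyRatingSeries("g2", base.copy(), np.full(30, 5))
        out = compare_daily_ratings(sa, sb)
        assert out["days_a_higher"] == 30
        assert out["days_b_higher"] == 0

    def test_group_gap_detected_at_small_alpha_in_most_simulations(self):
        # Monte-Carlo power oracle: gap 0.17, day-level sd 0.1, 30 days
        rng = np.random.default_rng(99)
        from tailorrec.trial_stats import DailyRatingSeries

        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            b = rng.normal(4.10, 0.1, 30)
            a = rng.normal(4.27, 0.1, 30)
            out = compare_daily_ratings(
                DailyRatingSeries("g1", a, np.full(30, 5)),
                DailyRatingSeries("g2", b, np.full(30, 5)),
            )
            hits += out["p"] < 0.001
        assert hits / n_sim > 0.90

    def test_mismatched_day_coverage_rejected(self):
        from tailorrec.trial_stats import DailyRatingSeries

        sa = DailyRatingSeries("g1", np.ones(30), np.ones(30, dtype=int))
        sb = DailyRatingSeries("g2", np.ones(29), np.ones(29, dtype=int))
        with pytest.raises(ValueError, match="day"):
            compare_daily_ratings(sa, sb)


class TestImpactDichotomization:
    @pytest.mark.parametrize(
        "value,expected", [(1, False), (3, False), (4, True), (5, True), (None, None)]
    )
    def test_agree_threshold_at_four(self, value, expected):
        rec = TrialRecord("u", "g", 0, (value, 3, 3, 3, 3, 3, 3), None)
        assert dichotomize_impact(rec)[0] is expected


class TestTables:
    def test_followup_percentages(self):
        assert percentage(30, 51) == pytest.approx(58.8, abs=0.05)
        assert percentage(19, 50) == pytest.approx(38.0, abs=0.05)
        assert percentage(35, 53) == pytest.approx(66.0, abs=0.05)
        assert percentage(46, 51) == pytest.approx(90.2, abs=0.05)

    def test_quit_table_chi_square_and_p(self):
        out = chi_square_2x2(QUIT_TABLE)
        assert out["chi2"] == pytest.approx(4.38, abs=0.01)
        assert out["p"] == pytest.approx(0.036, abs=0.001)

    def test_balanced_table_chi_square_zero(self):
        out = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert out["chi2"] == pytest.approx(0.0)

    def test_chi_square_matches_bruteforce_expected_counts(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cells = rng.integers(1, 60, 4)
            t = ContingencyTable2x2(*cells)
            arr = t.as_array()
            row, col, N = arr.sum(1), arr.sum(0), arr.sum()
            expected = np.outer(row, col) / N
            brute = ((arr - expected) ** 2 / expected).sum()
            assert chi_square_2x2(t)["chi2"] == pytest.approx(brute, rel=1e-10)

    def test_zero_margin_gives_missing_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero margin"):
            out = chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))
        assert math.isnan(out["chi2"])

    def test_quit_table_odds_ratio(self):
        out = odds_ratio_2x2(QUIT_TABLE)
        assert out["or"] == pytest.approx(2.33, abs=0.005)
        assert round(out["or"], 1) == 2.3
        assert not out["corrected"]

    def test_balanced_odds_ratio_is_one(self):
        assert odds_ratio_2x2(ContingencyTable2x2(10, 10, 10, 10))["or"] == 1.0

    def test_zero_cell_triggers_haldane_correction(self):
        out = odds_ratio_2x2(ContingencyTable2x2(5, 0, 3, 4))
        assert out["corrected"]
        assert out["or"] == pytest.approx((5.5 * 4.5) / (0.5 * 3.5))


class TestTrendTest:
    def test_flat_proportions_give_near_zero_statistic(self):
        out = trend_test_2xk([20, 20, 20], [100, 100, 100])
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_proportions_strongly_significant(self):
        out = trend_test_2xk([20, 50, 80], [100, 100, 100])
        assert out["p"] < 0.01

    def test_k_equals_two_reduces_to_pearson_chi_square(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(2, 50, 4)
            trend = trend_test_2xk([a, c], [a + b, c + d])
            chi = chi_square_2x2(ContingencyTable2x2(a, b, c, d))
            assert trend["statistic"] == pytest.approx(chi["chi2"], rel=1e-9)

    def test_fewer_than_two_levels_rejected(self):
        with pytest.raises(ValueError):
            trend_test_2xk([3], [10])


class TestLogistic:
    def test_single_binary_exposure_reproduces_cross_product_or(self):
        y = [1] * 30 + [0] * 21 + [1] * 19 + [0] * 31
        x = [1] * 51 + [0] * 50
        fit = fit_logistic(y, x)
        row = fit[fit.term == "exposure"].iloc[0]
        assert row["or"] == pytest.approx(odds_ratio_2x2(QUIT_TABLE)["or"], abs=1e-6)

    def test_null_outcome_gives_or_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 400)
        y = rng.integers(0, 2, 400)  # independent of x
        row = fit_logistic(y, x).iloc[0]
        assert row["or"] == pytest.approx(1.0, abs=0.5)
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_independent_covariate_leaves_exposure_or_stable(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.integers(0, 2, n)
        z = rng.normal(size=n)  # independent of both x and y|x
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))
        y = (rng.random(n) < p).astype(int)
        unadj = fit_logistic(y, x).iloc[0]["or"]
        adj = fit_logistic(y, x, {"z": z}).iloc[0]["or"]
        assert adj == pytest.approx(unadj, rel=0.05)

    def test_complete_separation_raises_naming_terms(self):
        y = [0, 0, 0, 1, 1, 1]
        x = [0, 0, 0, 1, 1, 1]
        with pytest.raises(ValueError, match="separation"):
            fit_logistic(y, x)


def simulate_mediation_frame(n, beta_tm, beta_direct, beta_med, seed):
    """Simple known-truth generator: m = 4 + beta_tm*t + e,
    logit P(y) = alpha + beta_direct*t + beta_med*m, with alpha anchored
    so control-arm prevalence stays moderate for any beta_med."""
    rng = np.random.default_rng(seed)
    t = rng.integers(0, 2, n).astype(float)
    m = 4.0 + beta_tm * t + rng.normal(0, 0.3, n)
    logit = -0.5 - beta_med * 4.0 + beta_direct * t + beta_med * m
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    return pd.DataFrame({"t": t, "m": m, "y": y})


class TestMediation:
    def test_severed_mediator_outcome_path_gives_near_zero_acme(self):
        df = simulate_mediation_frame(12000, beta_tm=0.5, beta_direct=0.7, beta_med=0.0, seed=1)
        res = mediation_analysis(df, "t", "m", "y", n_sims=400, seed=2)
        assert abs(res.acme) < 0.01
        assert abs(res.percent_mediated) < 6.0
        assert res.ci["acme"][0] <= 0.0 <= res.ci["acme"][1]

    def test_pure_indirect_path_gives_percent_near_100(self):
        df = simulate_mediation_frame(4000, beta_tm=0.8, beta_direct=0.0, beta_med=1.0, seed=2)
        res = mediation_analysis(df, "t", "m", "y", n_sims=400, seed=3)
        assert res.percent_mediated == pytest.approx(100.0, abs=12.0)

    def test_acme_plus_ade_equals_total_effect(self):
        df = simulate_mediation_frame(800, beta_tm=0.5, beta_direct=0.5, beta_med=0.8, seed=4)
        res = mediation_analysis(df, "t", "m", "y", n_sims=300, seed=5)
        # exact identity under the two-arm averaging convention
        assert res.acme + res.ade == pytest.approx(res.total_effect, abs=1e-12)

    def test_percent_mediated_invariant_to_mediator_rescaling(self):
        df = simulate_mediation_frame(1500, beta_tm=0.6, beta_direct=0.4, beta_med=0.9, seed=6)
        res1 = mediation_analysis(df, "t", "m", "y", n_sims=800, seed=7)
        df2 = df.assign(m=10.0 * df["m"] - 25.0)
        res2 = mediation_analysis(df2, "t", "m", "y", n_sims=800, seed=7)
        assert res2.percent_mediated == pytest.approx(res1.percent_mediated, abs=3.0)

    def test_unstable_total_effect_is_flagged(self):
        df = simulate_mediation_frame(120, beta_tm=0.1, beta_direct=0.0, beta_med=0.1, seed=8)
        with pytest.warns(RuntimeWarning, match="unstable"):
            res = mediation_analysis(df, "t", "m", "y", n_sims=300, seed=9)
        assert res.unstable

    def test_agrees_with_statsmodels_parametric_mediation(self):
        # independent cross-check against statsmodels' implementation of
        # the same quasi-Bayesian potential-outcome algorithm
        import statsmodels.api as sm
        from statsmodels.stats.mediation import Mediation

        df = simulate_mediation_frame(600, beta_tm=0.6, beta_direct=0.5, beta_med=0.9, seed=10)
        ours = mediation_analysis(df, "t", "m", "y", n_sims=1000, seed=11)
        out_mod = sm.GLM.from_formula(
            "y ~ t + m", df, family=sm.families.Binomial()
        )
        med_mod = sm.OLS.from_formula("m ~ t", df)
        ref = Mediation(out_mod, med_mod, "t", "m").fit(method="parametric", n_rep=600)
        summ = ref.summary()
        assert ours.acme == pytest.approx(
            summ.loc["ACME (average)", "Estimate"], abs=0.02
        )
        assert ours.total_effect == pytest.approx(
            summ.loc["Total effect", "Estimate"], abs=0.02
        )


class TestQuitTableBuilder:
    def test_complete_case_counts(self):
        recs = [
            TrialRecord("u1", "g1", 0, (None,) * 7, True),
            TrialRecord("u2", "g1", 0, (None,) * 7, False),
            TrialRecord("u3", "g1", 0, (None,) * 7, None),  # dropped
            TrialRecord("u4", "g2", 0, (None,) * 7, True),
        ]
        t = quit_table(recs, "g1", "g2")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 0)
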