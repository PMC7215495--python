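import math

import numpy as np
import pandas as pd
import pytest

from tailorrec.data_model import RatingMatrix
from tailorrec.eval_harness import (
    EvalReport,
    GridAxis,
    assert_no_leakage,
    compare_models,
    evaluate_protocol,
    grid_search,
    kendall_tau_b,
    make_strong_gen_splits,
    ndcg,
    rmse,
)
from tailorrec.recommenders import fit_knn, fit_pmf


# --- independent brute-force metric oracles --------------------------------


def brute_rmse(p, a):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(p, a)) / len(p))


def brute_tau_b(x, y):
    n = len(x)
    C = D = n1 = n2 = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0:
                n1 += 1
            if dy == 0:
                n2 += 1
            if dx != 0 and dy != 0:
                if dx * dy > 0:
                    C += 1
                else:
                    D += 1
    n0 = n * (n - 1) // 2
    return (C - D) / math.sqrt((n0 - n1) * (n0 - n2))


def brute_ndcg(ranked, ideal):
    def dcg(rels):
        return sum((2**r - 1) / math.log2(k + 2) for k, r in enumerate(rels))

    return dcg(ranked) / dcg(sorted(ideal, reverse=True))


# --- metrics ----------------------------------------------------------------


class TestMetrics:
    def test_rmse_examples(self):
        assert rmse([3, 4, 5], [3, 4, 5]) == 0.0
        assert rmse([4, 4], [3, 5]) == pytest.approx(1.0)
        # constant offset delta -> |delta|
        x = np.array([1.2, 2.7, 4.9])
        assert rmse(x + 0.4, x) == pytest.approx(0.4)
        with pytest.raises(ValueError):
            rmse([1, 2], [1])

    def test_tau_b_examples(self):
        x = [1, 2, 3, 4]
        assert kendall_tau_b(x, x) == pytest.approx(1.0)
        assert kendall_tau_b(x, x[::-1]) == pytest.approx(-1.0)
        # 6 pairs, 5 concordant 1 discordant -> 4/6
        assert kendall_tau_b([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(
            0.6667, abs=5e-5
        )

    def test_tau_b_all_tied_is_missing_with_warning(self):
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert math.isnan(kendall_tau_b([2, 2, 2], [1, 2, 3]))

    def test_ndcg_examples(self):
        assert ndcg([5, 4, 3, 1]) == pytest.approx(1.0)  # ideal order
        assert ndcg([3, 3, 3]) == pytest.approx(1.0)  # all tied: any order ideal
        # oracle: DCG = 7 + 31/log2(3) + 15/2 = 34.05881,
        # IDCG = 31 + 15/log2(3) + 7/2 = 43.96394 -> 0.77470
        assert ndcg([3, 5, 4], [5, 4, 3]) == pytest.approx(0.7747, abs=5e-5)
        with pytest.raises(ValueError):
            ndcg([])

    def test_metrics_match_bruteforce_on_random_vectors(self):
        # 100 random 20-element vectors per metric against the oracles
        rng = np.random.default_rng(123)
        for _ in range(100):
            p = rng.integers(1, 6, 20).astype(float)
            a = rng.integers(1, 6, 20).astype(float)
            assert rmse(p, a) == pytest.approx(brute_rmse(p, a), abs=1e-12)
            if not (np.all(p == p[0]) or np.all(a == a[0])):
                assert kendall_tau_b(p, a) == pytest.approx(
                    brute_tau_b(list(p), list(a)), abs=1e-12
                )
            assert ndcg(a) == pytest.approx(brute_ndcg(list(a), list(a)), abs=1e-12)
            assert 0.0 <= ndcg(a) <= 1.0


# --- splits -----------------------------------------------------------------


def complete_matrix(n_users=50, n_items=25):
    users = [f"u{i:02d}" for i in range(n_users)]
    items = [f"i{j:02d}" for j in range(n_items)]
    rng = np.random.default_rng(0)
    mat = RatingMatrix(users, items)
    for u in users:
        for m in items:
            mat.set(u, m, int(rng.integers(1, 6)))
    return mat


class TestSplits:
    def test_fifty_eligible_users_give_five_folds_of_ten(self):
        splits = make_strong_gen_splits(complete_matrix(), seed=1)
        assert len(splits) == 5
        all_test = []
        for s in splits:
            assert len(s.test_users) == 10
            assert len(s.validation) == 3
            all_test.extend(s.test_users)
            for u in s.test_users:
                assert len(s.test_ratings[u]) == 4
                sup = s.support[u]
                assert set(sup[5]) < set(sup[10]) < set(sup[16])  # nested
                test_items = {m for m, _ in s.test_ratings[u]}
                assert not test_items & set(sup[16])  # support/test disjoint
            assert not set(s.train_users) & set(s.test_users)
        assert sorted(all_test) == sorted(complete_matrix().users)

    def test_user_below_threshold_is_train_only(self):
        mat = complete_matrix(30, 25)
        thin = RatingMatrix(mat.users + ["thin"], mat.items)
        for u, m, v in mat.triplets():
            thin.set(u, m, v)
        for m in mat.items[:12]:
            thin.set("thin", m, 3)
        splits = make_strong_gen_splits(thin, seed=2)
        for s in splits:
            assert "thin" not in s.test_users
            assert "thin" in s.train_users

    def test_same_seed_gives_identical_splits(self):
        mat = complete_matrix()
        a = make_strong_gen_splits(mat, seed=5)
        b = make_strong_gen_splits(mat, seed=5)
        for sa, sb in zip(a, b):
            assert sa.test_users == sb.test_users
            assert sa.support == sb.support
            assert sa.test_ratings == sb.test_ratings
            assert sa.validation == sb.validation

    def test_too_few_eligible_users_is_an_error_naming_threshold(self):
        mat = complete_matrix(4, 25)
        with pytest.raises(ValueError, match="20 ratings"):
            make_strong_gen_splits(mat, seed=0)


# --- protocol + leakage -----------------------------------------------------


class TestProtocol:
    @pytest.fixture(scope="class")
    def report(self):
        mat = complete_matrix(30, 30)
        fitters = {
            "pmf": lambda m, s: fit_pmf(m, D=2, n_iter=20, seed=s),
            "knn": lambda m, s: fit_knn(m, k=5),
        }
        return evaluate_protocol(mat, fitters, seed=0)

    def test_report_covers_all_model_support_fold_cells(self, report):
        tab = report.table
        assert set(tab["model"]) == {"pmf", "knn"}
        assert set(tab["support"]) == {5, 10, 16}
        assert set(tab["fold"]) == {1, 2, 3, 4, 5}
        assert len(tab) == 2 * 3 * 5
        assert (tab["rmse"] >= 0).all()
        assert tab["ndcg"].between(0, 1).all()

    def test_no_test_rating_leaks_into_training_or_inference(self, report):
        assert report.test_pairs  # instrumentation captured something
        assert_no_leakage(report)

    def test_leakage_detector_fires_on_a_contaminated_audit(self, report):
        bad = EvalReport(
            table=report.table,
            used_pairs=report.used_pairs | set(list(report.test_pairs)[:1]),
            test_pairs=report.test_pairs,
        )
        with pytest.raises(AssertionError, match="leaked"):
            assert_no_leakage(bad)


# --- grid search ------------------------------------------------------------


class TestGridSearch:
    def _run(self, grid, loss, max_extensions=3):
        mat = complete_matrix(12, 25)
        split = make_strong_gen_splits(mat, seed=0, n_folds=2)[0]
        return grid_search(
            lambda **kw: (lambda m, s: fit_knn(m, k=2)),
            grid,
            mat,
            split,
            seed=0,
            max_extensions=max_extensions,
            score_fn=loss,
        )

    def test_single_point_grid_returns_it_without_extension(self):
        res = self._run({"lam": GridAxis([0.5])}, lambda p: p["lam"])
        assert res.best_params == {"lam": 0.5}
        assert res.n_extensions == 0 and not res.at_endpoint

    def test_interior_optimum_of_convex_curve_needs_no_extension(self):
        res = self._run(
            {"lam": GridAxis([1, 2, 4, 8])}, lambda p: (math.log2(p["lam"]) - 1.5) ** 2
        )
        assert res.best_params["lam"] in (2, 4)
        assert res.n_extensions == 0

    def test_optimum_at_right_endpoint_extends_geometrically(self):
        # loss decreasing up to 8: best of (1,2,4) is 4 -> extend to 8
        res = self._run({"lam": GridAxis([1, 2, 4])}, lambda p: abs(p["lam"] - 8))
        assert res.best_params["lam"] == 8
        assert res.n_extensions >= 1 and not res.at_endpoint

    def test_arithmetic_axis_extends_by_step(self):
        res = self._run(
            {"k": GridAxis([2, 4, 6], scale="arithmetic")}, lambda p: abs(p["k"] - 10)
        )
        assert res.best_params["k"] == 10

    def test_exhausted_extensions_return_flagged_best(self):
        with pytest.warns(RuntimeWarning, match="exhausted"):
            res = self._run(
                {"lam": GridAxis([1, 2])}, lambda p: -p["lam"], max_extensions=1
            )
        assert res.at_endpoint

    def test_grid_search_minimises_real_validation_rmse(self):
        # sanity: with a real objective the chosen k is the argmin over history
        mat = complete_matrix(14, 25)
        split = make_strong_gen_splits(mat, seed=1, n_folds=2)[0]
        res = grid_search(
            lambda k: (lambda m, s: fit_knn(m, k=int(k))),
            {"k": GridAxis([2, 3, 5], scale="arithmetic")},
            mat,
            split,
            seed=0,
        )
        best_hist = min(res.history, key=lambda t: t[1])
        assert res.best_score == best_hist[1]


# --- model comparison -------------------------------------------------------


def report_from(values: dict[str, list[float]]) -> EvalReport:
    rows = []
    for model, vals in values.items():
        for fold, v in enumerate(vals, start=1):
            rows.append(
                {"model": model, "support": 16, "fold": fold, "rmse": v,
                 "kendall_tau_b": 0.0, "ndcg": 1.0}
            )
    return EvalReport(table=pd.DataFrame(rows))


class TestCompareModels:
    def test_identical_vectors_give_t_zero_p_one(self):
        rep = report_from({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5]})
        row = compare_models(rep, "rmse").iloc[0]
        assert row["t"] == 0.0 and row["p_bonferroni"] == 1.0

    def test_constant_nonzero_difference_reports_missing_p_with_note(self):
        rep = report_from({"a": [1, 2, 3], "b": [1.5, 2.5, 3.5]})
        row = compare_models(rep, "rmse").iloc[0]
        assert math.isnan(row["p_bonferroni"])
        assert "zero-variance" in row["note"]

    def test_three_models_get_three_bonferroni_scaled_comparisons(self):
        rng = np.random.default_rng(0)
        rep = report_from({m: list(rng.normal(1 + i * 0.1, 0.05, 5)) for i, m in enumerate("abc")})
        tab = compare_models(rep, "rmse")
        assert len(tab) == 3
        ok = tab["p_raw"].notna()
        assert np.allclose(
            tab.loc[ok, "p_bonferroni"], np.minimum(1.0, tab.loc[ok, "p_raw"] * 3)
        )

    def test_mismatched_fold_sets_rejected(self):
        rep = report_from({"a": [1, 2, 3], "b": [1, 2, 3]})
        rep.table = rep.table[~((rep.table.model == "b") & (rep.table.fold == 3))]
        with pytest.raises(ValueError, match="fold"):
            compare_models(rep, "rmse")
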