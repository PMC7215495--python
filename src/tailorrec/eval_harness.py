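"""Cold-start ("strong generalization") evaluation of rating predictors.

The protocol separates test users from train users completely: a model is
fit on the train users' ratings only, all non-user parameters are frozen,
and each test user's parameters are inferred from a small *support* set of
their own ratings (5, 10 or 16, nested). Accuracy is then measured on a
constant set of 4 held-back test ratings per user. Users are split into 5
folds; 3 validation partitions per test fold (10% of each train user's
ratings held out) serve hyperparameter selection.

Metrics: RMSE on the predicted values, Kendall's tau-b (tie-corrected rank
correlation) and NDCG (exponential gain ``2^rel - 1``, ``log2(rank+1)``
discount) on the induced ranking. Models are compared by a two-sided
paired t test over fold-level metric values with Bonferroni adjustment
across all model pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import RatingMatrix
from .recommenders import (
    ColdUserFactor,
    FactorModel,
    KnnModel,
    infer_user_factors,
    predict_knn_from_ratings,
    score_candidates,
)

__all__ = [
    "StrongGenSplit",
    "EvalReport",
    "GridAxis",
    "GridSearchResult",
    "make_strong_gen_splits",
    "rmse",
    "kendall_tau_b",
    "ndcg",
    "evaluate_protocol",
    "grid_search",
    "compare_models",
    "assert_no_leakage",
]

SUPPORT_LEVELS = (5, 10, 16)
N_TEST_RATINGS = 4
N_FOLDS = 5
N_VALIDATION = 3


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def rmse(predicted: Sequence[float], actual: Sequence[float]) -> float:
    """Root mean squared error between two equal-length vectors."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ValueError(f"need equal-length nonempty vectors, got {p.size} vs {a.size}")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b, the tie-corrected rank correlation.

    Returns NaN (with a warning) when either vector is entirely tied —
    the coefficient is undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("tau-b undefined for an all-tied vector", RuntimeWarning)
        return float("nan")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def _dcg(relevances: np.ndarray) -> float:
    gains = 2.0**relevances - 1.0
    discounts = np.log2(np.arange(2, relevances.size + 2))
    return float((gains / discounts).sum())


def ndcg(
    ranked_relevances: Sequence[float],
    ideal_relevances: Optional[Sequence[float]] = None,
    cutoff: Optional[int] = None,
) -> float:
    """Normalized discounted cumulative gain.

    ``ranked_relevances`` are the true ratings of the items in predicted
    rank order; the ideal ordering (by default the same relevances sorted
    descending) defines the normaliser. With all relevances equal every
    permutation scores 1.
    """
    rel = np.asarray(ranked_relevances, dtype=float)
    if rel.size == 0:
        raise ValueError("empty relevance list")
    ideal = (
        np.sort(rel)[::-1]
        if ideal_relevances is None
        else np.sort(np.asarray(ideal_relevances, dtype=float))[::-1]
    )
    if cutoff is not None:
        rel = rel[:cutoff]
        ideal = ideal[:cutoff]
    denom = _dcg(ideal)
    if denom == 0.0:
        return 1.0  # all-zero relevances: any order is ideal
    return float(_dcg(rel) / denom)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass
class StrongGenSplit:
    """One user fold of the cold-start protocol.

    ``support`` maps each test user to nested item-id lists per support
    size; ``test_ratings`` maps each test user to exactly 4 (item, value)
    pairs disjoint from every support set. ``validation`` holds 3
    partitions, each a map train_user -> held-out item ids.
    """

    fold_id: int
    train_users: list[str]
    test_users: list[str]
    support: dict[str, dict[int, list[str]]]
    test_ratings: dict[str, list[tuple[str, float]]]
    validation: list[dict[str, list[str]]]


def make_strong_gen_splits(
    matrix: RatingMatrix,
    seed: int = 0,
    n_folds: int = N_FOLDS,
    support_sizes: Sequence[int] = SUPPORT_LEVELS,
    n_test: int = N_TEST_RATINGS,
    n_validation: int = N_VALIDATION,
    validation_frac: float = 0.1,
) -> list[StrongGenSplit]:
    """Deterministically build the user folds of the cold-start protocol.

    A user is eligible as a *test* user only with at least
    ``max(support_sizes) + n_test`` ratings (20 under the defaults); users
    below that threshold still contribute to every training fold.
    """
    support_sizes = sorted(support_sizes)
    min_needed = support_sizes[-1] + n_test
    counts = {u: len(matrix.user_ratings(u)) for u in matrix.users}
    eligible = [u for u in matrix.users if counts[u] >= min_needed]
    if len(eligible) < n_folds:
        raise ValueError(
            f"only {len(eligible)} users have >= {min_needed} ratings "
            f"({support_sizes[-1]} support + {n_test} test); "
            f"need at least {n_folds} eligible test users"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(eligible))
    folds: list[list[str]] = [order[f::n_folds] for f in range(n_folds)]
    splits: list[StrongGenSplit] = []
    for f, test_users in enumerate(folds, start=1):
        test_set = set(test_users)
        train_users = [u for u in matrix.users if u not in test_set]
        support: dict[str, dict[int, list[str]]] = {}
        test_ratings: dict[str, list[tuple[str, float]]] = {}
        for u in sorted(test_users):
            ratings = matrix.user_ratings(u)
            items = sorted(ratings)
            perm = list(rng.permutation(items))
            test_items = perm[:n_test]
            pool = perm[n_test:]
            support[u] = {s: pool[:s] for s in support_sizes}
            test_ratings[u] = [(m, ratings[m]) for m in test_items]
        validation: list[dict[str, list[str]]] = []
        for _ in range(n_validation):
            part: dict[str, list[str]] = {}
            for u in train_users:
                items = sorted(matrix.user_ratings(u))
                n_hold = max(1, math.ceil(validation_frac * len(items))) if items else 0
                if n_hold and len(items) > n_hold:
                    part[u] = list(rng.permutation(items)[:n_hold])
            validation.append(part)
        splits.append(
            StrongGenSplit(
                fold_id=f,
                train_users=train_users,
                test_users=sorted(test_users),
                support=support,
                test_ratings=test_ratings,
                validation=validation,
            )
        )
    return splits


# ---------------------------------------------------------------------------
# Protocol evaluation
# ---------------------------------------------------------------------------

#: A fitter takes (train matrix, seed) and returns a fitted model.
Fitter = Callable[[RatingMatrix, int], FactorModel | KnnModel]


def _cold_predict(
    model: FactorModel | KnnModel,
    support_ratings: Mapping[str, float],
    items: Sequence[str],
    seed: int,
) -> list[float]:
    if isinstance(model, KnnModel):
        return [predict_knn_from_ratings(model, support_ratings, m) for m in items]
    factor = infer_user_factors(model, support_ratings, seed=seed)
    return [float(v) for v in score_candidates(model, factor, items)]


@dataclass
class EvalReport:
    """Per (model, support level, fold) metric table plus a leakage audit.

    ``used_pairs`` records every (fold, user, item) rating consumed during
    fitting or user-factor inference in that fold; ``test_pairs`` the
    held-back cells per fold. The audit is fold-scoped: a test user's
    held-back cells are banned within their own fold, while the same
    user's full rating set legitimately enters training in the folds
    where they serve as a train user.
    """

    table: pd.DataFrame
    used_pairs: set[tuple[int, str, str]] = field(default_factory=set)
    test_pairs: set[tuple[int, str, str]] = field(default_factory=set)

    def aggregate(self) -> pd.DataFrame:
        return (
            self.table.groupby(["model", "support"])[["rmse", "kendall_tau_b", "ndcg"]]
            .mean()
            .reset_index()
        )


def evaluate_protocol(
    matrix: RatingMatrix,
    fitters: Mapping[str, Fitter],
    splits: Sequence[StrongGenSplit] | None = None,
    support_sizes: Sequence[int] = SUPPORT_LEVELS,
    seed: int = 0,
) -> EvalReport:
    """Run the cold-start protocol for each model family.

    Per fold: fit on the train users only, then for each test user infer
    user parameters from the support ratings and predict the 4 test
    ratings. Fold-level RMSE pools all test predictions in the fold;
    tau-b and NDCG are averaged per user (NaN tau-b from tied 4-vectors
    is ignored in the average).
    """
    if splits is None:
        splits = make_strong_gen_splits(matrix, seed=seed, support_sizes=support_sizes)
    rows = []
    used: set[tuple[int, str, str]] = set()
    test_pairs: set[tuple[int, str, str]] = set()
    for split in splits:
        train = matrix.subset_users(split.train_users)
        used.update((split.fold_id, u, m) for u, m, _ in train.triplets())
        for u, pairs in split.test_ratings.items():
            test_pairs.update((split.fold_id, u, m) for m, _ in pairs)
        for name, fitter in fitters.items():
            model = fitter(train, seed)
            for s in support_sizes:
                preds, actuals = [], []
                taus, ndcgs = [], []
                for u in split.test_users:
                    sup_items = split.support[u][s]
                    ratings = matrix.user_ratings(u)
                    support_ratings = {m: ratings[m] for m in sup_items}
                    used.update((split.fold_id, u, m) for m in sup_items)
                    t_items = [m for m, _ in split.test_ratings[u]]
                    t_vals = [v for _, v in split.test_ratings[u]]
                    p = _cold_predict(model, support_ratings, t_items, seed)
                    preds.extend(p)
                    actuals.extend(t_vals)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        tau = kendall_tau_b(p, t_vals)
                    if not math.isnan(tau):
                        taus.append(tau)
                    order = np.argsort(np.argsort(-np.asarray(p), kind="stable"))
                    ranked = [v for _, v in sorted(zip(order, t_vals))]
                    ndcgs.append(ndcg(ranked, t_vals))
                rows.append(
                    {
                        "model": name,
                        "support": s,
                        "fold": split.fold_id,
                        "rmse": rmse(preds, actuals),
                        "kendall_tau_b": float(np.mean(taus)) if taus else float("nan"),
                        "ndcg": float(np.mean(ndcgs)),
                    }
                )
    return EvalReport(table=pd.DataFrame(rows), used_pairs=used, test_pairs=test_pairs)


def assert_no_leakage(report: EvalReport) -> None:
    """Raise if any held-back test rating was consumed during fitting or
    user-factor inference anywhere in the protocol."""
    leaked = report.used_pairs & report.test_pairs
    if leaked:
        raise AssertionError(f"test ratings leaked into training: {sorted(leaked)[:5]}")


# ---------------------------------------------------------------------------
# Hyperparameter grid search with iterative range extension
# ---------------------------------------------------------------------------


@dataclass
class GridAxis:
    """One hyperparameter axis. ``scale`` controls how the range is
    extended when the optimum lands on an endpoint: geometric for scale
    parameters (regularizers), arithmetic for counts (k, rank)."""

    values: list[float]
    scale: str = "geometric"  # or "arithmetic"

    def extend_low(self) -> float:
        v = sorted(self.values)
        if self.scale == "geometric":
            ratio = v[1] / v[0] if len(v) > 1 and v[0] > 0 else 2.0
            return v[0] / max(ratio, 1.0 + 1e-9)
        step = v[1] - v[0] if len(v) > 1 else 1.0
        return v[0] - step

    def extend_high(self) -> float:
        v = sorted(self.values)
        if self.scale == "geometric":
            ratio = v[-1] / v[-2] if len(v) > 1 and v[-2] > 0 else 2.0
            return v[-1] * max(ratio, 1.0 + 1e-9)
        step = v[-1] - v[-2] if len(v) > 1 else 1.0
        return v[-1] + step


@dataclass
class GridSearchResult:
    best_params: dict[str, float]
    best_score: float
    n_extensions: int
    at_endpoint: bool  # best still on an endpoint after max_extensions
    history: list[tuple[dict[str, float], float]]


def _validation_rmse(
    fit_factory: Callable[..., Fitter],
    params: Mapping[str, float],
    matrix: RatingMatrix,
    split: StrongGenSplit,
    seed: int,
) -> float:
    """Mean RMSE over the split's validation partitions: fit on train
    ratings minus the held-out cells, score the held-out cells."""
    fitter = fit_factory(**params)
    scores = []
    train = matrix.subset_users(split.train_users)
    for part in split.validation:
        reduced = RatingMatrix(train.users, train.items)
        held: list[tuple[str, str, float]] = []
        for u, m, v in train.triplets():
            if m in part.get(u, ()):
                held.append((u, m, v))
            else:
                reduced.set(u, m, v)
        if not held:
            continue
        model = fitter(reduced, seed)
        by_user: dict[str, list[tuple[str, float]]] = {}
        for u, m, v in held:
            by_user.setdefault(u, []).append((m, v))
        preds, actuals = [], []
        for u, pairs in by_user.items():
            support = reduced.user_ratings(u)
            items = [m for m, _ in pairs]
            preds.extend(_cold_predict(model, support, items, seed))
            actuals.extend(v for _, v in pairs)
        scores.append(rmse(preds, actuals))
    return float(np.mean(scores))


def grid_search(
    fit_factory: Callable[..., Fitter],
    grid: Mapping[str, GridAxis],
    matrix: RatingMatrix,
    split: StrongGenSplit,
    seed: int = 0,
    max_extensions: int = 3,
    score_fn: Optional[Callable[[dict[str, float]], float]] = None,
) -> GridSearchResult:
    """Exhaustive grid search minimising mean validation RMSE.

    If the selected value of any axis sits at an endpoint of its current
    range, the range is extended in that direction (geometrically or
    arithmetically per the axis) and the search repeats, up to
    ``max_extensions`` times; exhausting the budget with the optimum
    still at an endpoint returns it flagged, with a warning.

    ``score_fn`` overrides the validation-RMSE objective (used by tests
    to probe the extension logic with an analytic loss).
    """
    if not grid or any(not ax.values for ax in grid.values()):
        raise ValueError("every grid axis needs at least one value")
    grid = {k: GridAxis(sorted(set(ax.values)), ax.scale) for k, ax in grid.items()}
    history: list[tuple[dict[str, float], float]] = []
    cache: dict[tuple, float] = {}

    def score(params: dict[str, float]) -> float:
        key = tuple(sorted(params.items()))
        if key not in cache:
            if score_fn is not None:
                cache[key] = float(score_fn(params))
            else:
                cache[key] = _validation_rmse(fit_factory, params, matrix, split, seed)
            history.append((dict(params), cache[key]))
        return cache[key]

    n_ext = 0
    while True:
        names = list(grid)
        best_params, best_score = None, np.inf
        stack: list[dict[str, float]] = [{}]
        for name in names:
            stack = [dict(p, **{name: v}) for p in stack for v in grid[name].values]
        for params in stack:
            s = score(params)
            if s < best_score:
                best_params, best_score = params, s
        assert best_params is not None
        endpoint_axes = []
        for name, ax in grid.items():
            if len(ax.values) < 2:
                continue  # a single-point axis has no interior
            v = best_params[name]
            if v == min(ax.values):
                endpoint_axes.append((name, "low"))
            elif v == max(ax.values):
                endpoint_axes.append((name, "high"))
        if not endpoint_axes:
            return GridSearchResult(best_params, best_score, n_ext, False, history)
        if n_ext >= max_extensions:
            warnings.warn(
                f"grid search exhausted {max_extensions} extensions with the "
                f"optimum still at endpoint(s) {endpoint_axes}",
                RuntimeWarning,
            )
            return GridSearchResult(best_params, best_score, n_ext, True, history)
        for name, side in endpoint_axes:
            ax = grid[name]
            new = ax.extend_low() if side == "low" else ax.extend_high()
            ax.values = sorted(set(ax.values + [new]))
        n_ext += 1


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


def compare_models(
    report: EvalReport, metric: str = "rmse", support: Optional[int] = None
) -> pd.DataFrame:
    """Pairwise two-sided paired t tests over fold-level metric values.

    Raw p-values are Bonferroni-adjusted by the number of model pairs
    (capped at 1). A pair whose fold-level differences have zero variance
    is degenerate for the t statistic: identical vectors report t=0 and
    adjusted p=1; a constant nonzero difference reports p as missing with
    an explanatory note.
    """
    tab = report.table
    if support is not None:
        tab = tab[tab["support"] == support]
    tab = tab.groupby(["model", "fold"])[metric].mean().unstack("fold")
    models = list(tab.index)
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    if tab.isna().any().any():
        raise ValueError("models were not evaluated on identical fold sets")
    pairs = [(a, b) for i, a in enumerate(models) for b in models[i + 1 :]]
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        x, y = tab.loc[a].to_numpy(), tab.loc[b].to_numpy()
        d = x - y
        note = ""
        if np.allclose(d.var(), 0.0):
            if np.allclose(d, 0.0):
                t, p_raw, p_adj = 0.0, 1.0, 1.0
            else:
                t, p_raw, p_adj = float("nan"), float("nan"), float("nan")
                note = "zero-variance nonzero difference; t undefined"
        else:
            res = stats.ttest_rel(x, y)
            t, p_raw = float(res.statistic), float(res.pvalue)
            p_adj = min(1.0, p_raw * n_comp)
        rows.append(
            {
                "model_a": a,
                "model_b": b,
                "mean_a": float(x.mean()),
                "mean_b": float(y.mean()),
                "t": t,
                "p_raw": p_raw,
                "p_bonferroni": p_adj,
                "note": note,
            }
        )
    return pd.DataFrame(rows)
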