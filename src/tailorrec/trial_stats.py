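"""Statistics for a two-group tailored-messaging trial.

The analysis chain follows the flow of data collection:

1. **During the intervention** — a *daily rating* per group (mean of the
   ratings submitted by that group's members on each study day), compared
   between groups with a t test; engagement as mean website visits.
2. **At follow-up** — the seven intervention-impact items, dichotomized
   (agree/strongly agree, i.e. rating >= 4, versus other) and compared by
   Pearson chi-square; 30-day cessation as a 2x2 table, a cross-product
   odds ratio with Wald CI, and a logistic model with group as exposure.
3. **Mediation** — a quasi-Bayesian potential-outcome decomposition of
   the group effect on cessation into the part transmitted through the
   mediator (each user's mean daily rating) and the direct remainder,
   reported as the percent of the total effect mediated.

Baseline tables use Pearson chi-square for nominal rows and a
Mantel-extension (Cochran-Armitage) score test for trend across ordered
rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data_model import N_IMPACT_ITEMS, RatingEvent, TrialRecord

__all__ = [
    "DailyRatingSeries",
    "ContingencyTable2x2",
    "MediationResult",
    "daily_group_means",
    "compare_daily_ratings",
    "compare_visits",
    "dichotomize_impact",
    "impact_table",
    "quit_table",
    "percentage",
    "chi_square_2x2",
    "odds_ratio_2x2",
    "trend_test_2xk",
    "fit_logistic",
    "mediation_analysis",
]


# ---------------------------------------------------------------------------
# Daily ratings
# ---------------------------------------------------------------------------


@dataclass
class DailyRatingSeries:
    """Per-day mean rating for one group over the 30 message days.

    Days on which nobody in the group rated are NaN (missing), never 0.
    """

    group: str
    means: np.ndarray  # length n_days, NaN where no raters
    n_raters: np.ndarray  # length n_days, int

    @property
    def n_days(self) -> int:
        return int(self.means.size)

    def prop_days_ge(self, threshold: float = 4.0) -> float:
        """Proportion of non-missing days with mean rating >= threshold
        (the "agree or strongly agree" daily criterion)."""
        ok = ~np.isnan(self.means)
        if not ok.any():
            return float("nan")
        return float((self.means[ok] >= threshold).mean())


def daily_group_means(
    events: Sequence[RatingEvent],
    roster: Mapping[str, str],
    n_days: int = 30,
) -> dict[str, DailyRatingSeries]:
    """Group-wise daily mean ratings over non-missing replies only.

    ``roster`` maps user_id -> group label. Sent-but-unrated events
    (value None) do not contribute; a (group, day) with no ratings is
    recorded as missing.
    """
    groups = sorted(set(roster.values()))
    acc: dict[str, list[list[float]]] = {g: [[] for _ in range(n_days)] for g in groups}
    for e in events:
        if e.value is None or e.day_index > n_days:
            continue
        g = roster.get(e.user_id)
        if g is None:
            raise KeyError(f"user {e.user_id!r} missing from roster")
        acc[g][e.day_index - 1].append(float(e.value))
    out = {}
    for g in groups:
        means = np.array(
            [np.mean(day) if day else np.nan for day in acc[g]], dtype=float
        )
        ns = np.array([len(day) for day in acc[g]], dtype=int)
        out[g] = DailyRatingSeries(group=g, means=means, n_raters=ns)
    return out


def compare_daily_ratings(
    series_a: DailyRatingSeries,
    series_b: DailyRatingSeries,
    equal_var: bool = True,
) -> dict:
    """Compare two groups' daily-rating series.

    Reports how many days group *a* rated higher, each group's proportion
    of days with mean >= 4, and a two-sample t test on the daily means
    (pooled-variance by default, Welch with ``equal_var=False``).
    """
    if series_a.n_days != series_b.n_days:
        raise ValueError(
            f"series cover different day ranges "
            f"({series_a.n_days} vs {series_b.n_days} days)"
        )
    both = ~np.isnan(series_a.means) & ~np.isnan(series_b.means)
    a, b = series_a.means[both], series_b.means[both]
    if a.var() == 0.0 and b.var() == 0.0:
        # degenerate constant series: equal means are a null result
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return {
        "days_a_higher": int((a > b).sum()),
        "days_b_higher": int((b > a).sum()),
        "n_days_compared": int(both.sum()),
        "prop_days_ge4": {
            series_a.group: series_a.prop_days_ge(4.0),
            series_b.group: series_b.prop_days_ge(4.0),
        },
        "mean": {series_a.group: float(a.mean()), series_b.group: float(b.mean())},
        "t": float(t),
        "p": float(p),
    }


def compare_visits(
    records: Sequence[TrialRecord], group_a: str, group_b: str, equal_var: bool = True
) -> dict:
    """t test on mean website visits between the two groups."""
    va = [r.website_visits for r in records if r.group == group_a]
    vb = [r.website_visits for r in records if r.group == group_b]
    t, p = stats.ttest_ind(va, vb, equal_var=equal_var)
    return {
        "mean": {group_a: float(np.mean(va)), group_b: float(np.mean(vb))},
        "t": float(t),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# Impact items and 2x2 tables
# ---------------------------------------------------------------------------


def dichotomize_impact(record: TrialRecord) -> tuple[Optional[bool], ...]:
    """Agree/strongly-agree split of the seven impact items.

    True iff the reply is >= 4; missing stays missing (and is excluded
    from any denominator downstream).
    """
    return tuple(None if v is None else v >= 4 for v in record.impact_items)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = group and columns = outcome (yes, no):
    ``a``/``b`` are group-1 yes/no, ``c``/``d`` group-2 yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def percentage(numerator: int, denominator: int) -> float:
    """A printed-style percentage, e.g. 30/51 -> 58.8."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * numerator / denominator


def quit_table(
    records: Sequence[TrialRecord], group_1: str, group_2: str
) -> ContingencyTable2x2:
    """30-day cessation 2x2 from trial records, complete-case (records
    with a missing cessation flag are dropped)."""

    def cells(g: str) -> tuple[int, int]:
        flags = [r.quit_30day for r in records if r.group == g and r.quit_30day is not None]
        return sum(flags), len(flags) - sum(flags)

    a, b = cells(group_1)
    c, d = cells(group_2)
    return ContingencyTable2x2(a, b, c, d)


def impact_table(
    records: Sequence[TrialRecord], item: int, group_1: str, group_2: str
) -> ContingencyTable2x2:
    """Dichotomized 2x2 for impact item ``item`` (1-based), complete-case."""
    if not 1 <= item <= N_IMPACT_ITEMS:
        raise ValueError(f"item must be 1..{N_IMPACT_ITEMS}")

    def cells(g: str) -> tuple[int, int]:
        vals = [
            dichotomize_impact(r)[item - 1]
            for r in records
            if r.group == g and r.impact_items[item - 1] is not None
        ]
        return sum(bool(v) for v in vals), len(vals) - sum(bool(v) for v in vals)

    a, b = cells(group_1)
    c, d = cells(group_2)
    return ContingencyTable2x2(a, b, c, d)


def chi_square_2x2(table: ContingencyTable2x2) -> dict:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    A zero margin leaves the statistic undefined; both values come back
    NaN with a warning.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin: chi-square undefined", RuntimeWarning)
        return {"chi2": float("nan"), "p": float("nan")}
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return {"chi2": float(chi2), "p": float(p)}


def odds_ratio_2x2(table: ContingencyTable2x2, z: float = 1.959963984540054) -> dict:
    """Cross-product odds ratio ``ad/bc`` with a 95% Wald interval.

    A zero cell triggers the Haldane-Anscombe correction (+0.5 to every
    cell), flagged in the result.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    corrected = 0 in (table.a, table.b, table.c, table.d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orr) - z * se), np.exp(np.log(orr) + z * se)
    return {"or": float(orr), "ci": (float(lo), float(hi)), "corrected": corrected}


def trend_test_2xk(
    successes: Sequence[int], totals: Sequence[int], scores: Optional[Sequence[float]] = None
) -> dict:
    """Score test for linear trend in proportions across ordered categories
    (the Mantel-extension / Cochran-Armitage trend statistic, df=1).

    ``successes[i]`` of ``totals[i]`` subjects at ordered level i; scores
    default to 0, 1, 2, .... With k=2 and scores (0, 1) the statistic
    equals the Pearson chi-square of the corresponding 2x2 table.
    """
    s = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if s.size != n.size or s.size < 2:
        raise ValueError("need k >= 2 ordered categories")
    if np.any(s > n) or np.any(s < 0):
        raise ValueError("successes must be within 0..totals")
    x = np.arange(s.size, dtype=float) if scores is None else np.asarray(scores, float)
    N, A = n.sum(), s.sum()
    if A == 0 or A == N:
        warnings.warn("all or no successes: trend statistic undefined", RuntimeWarning)
        return {"statistic": float("nan"), "p": float("nan")}
    pbar = A / N
    T = float((x * s).sum())
    E = pbar * float((x * n).sum())
    V = pbar * (1 - pbar) * (float((n * x**2).sum()) - float((n * x).sum()) ** 2 / N)
    stat = (T - E) ** 2 / V
    return {"statistic": float(stat), "p": float(stats.chi2.sf(stat, df=1))}


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


def fit_logistic(
    outcome: Sequence[int],
    exposure: Sequence[float],
    covariates: Optional[Mapping[str, Sequence[float]]] = None,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Maximum-likelihood logistic regression of a binary outcome on an
    exposure plus optional covariates.

    Returns one row per term (exposure first) with the coefficient, the
    exponentiated coefficient (odds ratio) and its 95% Wald interval.
    Complete separation and non-convergence raise, naming the design.
    """
    y = np.asarray(outcome, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    cols = {"exposure": np.asarray(exposure, dtype=float)}
    for name, v in (covariates or {}).items():
        cols[name] = np.asarray(v, dtype=float)
    X = pd.DataFrame(cols)
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=max_iter)
    except (
        sm.tools.sm_exceptions.PerfectSeparationError,
        sm.tools.sm_exceptions.PerfectSeparationWarning,
    ) as err:
        raise ValueError(
            f"complete separation in logistic model with terms {list(X.columns)}"
        ) from err
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(f"logistic fit did not converge within {max_iter} iterations")
    ci = fit.conf_int()
    rows = []
    for term in ["exposure", *(covariates or {}), "const"]:
        rows.append(
            {
                "term": term,
                "coef": float(fit.params[term]),
                "or": float(np.exp(fit.params[term])),
                "ci_low": float(np.exp(ci.loc[term, 0])),
                "ci_high": float(np.exp(ci.loc[term, 1])),
                "p": float(fit.pvalues[term]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Causal mediation
# ---------------------------------------------------------------------------


@dataclass
class MediationResult:
    """Potential-outcome decomposition of the group effect on cessation.

    All effects are on the outcome-probability scale. ``percent_mediated``
    is 100 * ACME / total effect (each averaged over the two treatment
    arms); ``unstable`` flags a total-effect CI spanning zero, where the
    percentage is ill-determined.
    """

    acme: float
    ade: float
    total_effect: float
    percent_mediated: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_simulations: int = 0
    unstable: bool = False


def mediation_analysis(
    data: pd.DataFrame,
    treatment: str,
    mediator: str,
    outcome: str,
    covariates: Sequence[str] = (),
    n_sims: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Quasi-Bayesian causal mediation with a continuous mediator and a
    binary outcome.

    Two models are fit: a linear regression of the mediator on treatment
    (plus covariates) and a logistic regression of the outcome on
    treatment, mediator and covariates. ``n_sims`` parameter vectors are
    then drawn from each fit's asymptotic normal sampling distribution;
    for every draw, potential mediator values under treatment and control
    are simulated (with the linear model's estimated residual SD) and
    outcome probabilities computed for the four treatment x mediator
    combinations. The average causal mediation effect (ACME) is the
    effect of switching the mediator's potential value while holding
    treatment; the direct effect (ADE) switches treatment holding the
    mediator; the total effect switches both. Effects are averaged over
    the two treatment arms, and percentile CIs come from the draws.
    """
    cols = [treatment, mediator, outcome, *covariates]
    d = data[cols].dropna().reset_index(drop=True)
    t = d[treatment].to_numpy(dtype=float)
    if not set(np.unique(t)) <= {0.0, 1.0}:
        raise ValueError("treatment must be binary 0/1")
    n = len(d)
    Z = d[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((n, 0))

    # mediator model: m ~ 1 + t + Z
    Xm = np.column_stack([np.ones(n), t, Z])
    med_fit = sm.OLS(d[mediator].to_numpy(dtype=float), Xm).fit()
    sigma = float(np.sqrt(med_fit.scale))

    # outcome model: y ~ 1 + t + m + Z
    Xy = np.column_stack([np.ones(n), t, d[mediator].to_numpy(dtype=float), Z])
    out_fit = sm.Logit(d[outcome].to_numpy(dtype=float), Xy).fit(disp=0)

    rng = np.random.default_rng(seed)
    beta_m = rng.multivariate_normal(med_fit.params, med_fit.cov_params(), size=n_sims)
    beta_y = rng.multivariate_normal(out_fit.params, out_fit.cov_params(), size=n_sims)

    ones = np.ones(n)
    Xm0 = np.column_stack([ones, np.zeros(n), Z])
    Xm1 = np.column_stack([ones, ones, Z])

    def expit(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    acme_draws = np.empty(n_sims)
    ade_draws = np.empty(n_sims)
    total_draws = np.empty(n_sims)
    for k in range(n_sims):
        m0 = Xm0 @ beta_m[k] + rng.normal(0.0, sigma, n)
        m1 = Xm1 @ beta_m[k] + rng.normal(0.0, sigma, n)
        b = beta_y[k]

        def prob(t_val: float, m: np.ndarray) -> np.ndarray:
            lin = b[0] + b[1] * t_val + b[2] * m
            if Z.shape[1]:
                lin = lin + Z @ b[3:]
            return expit(lin)

        delta0 = (prob(0.0, m1) - prob(0.0, m0)).mean()
        delta1 = (prob(1.0, m1) - prob(1.0, m0)).mean()
        zeta0 = (prob(1.0, m0) - prob(0.0, m0)).mean()
        zeta1 = (prob(1.0, m1) - prob(0.0, m1)).mean()
        acme_draws[k] = 0.5 * (delta0 + delta1)
        ade_draws[k] = 0.5 * (zeta0 + zeta1)
        total_draws[k] = (prob(1.0, m1) - prob(0.0, m0)).mean()

    def ci(v: np.ndarray) -> tuple[float, float]:
        lo, hi = np.percentile(v, [2.5, 97.5])
        return float(lo), float(hi)

    acme = float(acme_draws.mean())
    ade = float(ade_draws.mean())
    total = float(total_draws.mean())
    total_ci = ci(total_draws)
    unstable = total_ci[0] <= 0.0 <= total_ci[1]
    if unstable:
        warnings.warn(
            "total-effect CI spans 0; percent mediated is unstable",
            RuntimeWarning,
        )
    pct = 100.0 * acme / total if total != 0 else float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_draws = 100.0 * acme_draws / total_draws
    return MediationResult(
        acme=acme,
        ade=ade,
        total_effect=total,
        percent_mediated=float(pct),
        ci={
            "acme": ci(acme_draws),
            "ade": ci(ade_draws),
            "total_effect": total_ci,
            "percent_mediated": ci(pct_draws[np.isfinite(pct_draws)]),
        },
        n_simulations=n_sims,
        unstable=unstable,
    )
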