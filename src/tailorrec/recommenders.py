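"""Collaborative-filtering engines over a sparse Likert rating matrix.

Three model families, all predicting a user's 1-5 "influence on quitting"
reply to a message they have not yet seen:

* **user-kNN** — Pearson similarity between users computed over co-rated
  messages; prediction is the target user's mean plus a similarity-weighted
  average of the neighbours' mean-centred ratings.
* **PMF** — probabilistic matrix factorization, fit as the MAP estimate of
  a regularized squared-error objective via alternating least squares
  (deterministic given the seed used for initialisation).
* **BPMF** — Bayesian PMF: Gibbs sampling over user and item factor
  matrices with Gaussian-Wishart hyperpriors; a prediction is the mean of
  u·v over the retained posterior draws, i.e. the expected value of the
  user-item factor product under embedding uncertainty.

Cold-start ("strong generalization") support: :func:`infer_user_factors`
estimates a *new* user's factor from a handful of their ratings while
leaving every non-user parameter — item factors, hyperparameters — frozen.

All predictions are clipped to the [1, 5] Likert range; an unbounded dot
product is meaningless to rank against the reply scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import wishart

from .data_model import RatingMatrix

__all__ = [
    "Prediction",
    "KnnModel",
    "FactorModel",
    "ColdUserFactor",
    "fit_knn",
    "predict_knn",
    "predict_knn_from_ratings",
    "fit_pmf",
    "fit_bpmf",
    "infer_user_factors",
    "predict",
    "predict_from_factor",
    "score_candidates",
    "rank_messages",
    "save_model",
    "load_model",
]

RATING_MIN, RATING_MAX = 1.0, 5.0


def _clip(x: float) -> float:
    return float(min(RATING_MAX, max(RATING_MIN, x)))


@dataclass(frozen=True)
class Prediction:
    user_id: str
    message_id: str
    value: float

    def __post_init__(self) -> None:
        if not (RATING_MIN <= self.value <= RATING_MAX):
            raise ValueError(f"prediction {self.value} outside [1, 5]")


# ---------------------------------------------------------------------------
# user-kNN
# ---------------------------------------------------------------------------


@dataclass
class KnnModel:
    """User-based nearest-neighbour model.

    ``similarity`` is symmetric with unit diagonal; a pair with fewer than
    ``min_overlap`` co-rated messages gets similarity 0 by convention.
    """

    k: int
    min_overlap: int
    user_ids: list[str]
    item_ids: list[str]
    similarity: np.ndarray
    user_means: np.ndarray
    dense: np.ndarray  # users x items, NaN where unobserved
    item_means: np.ndarray  # NaN for never-rated items
    global_mean: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        # a constant vector has no linear association to measure
        return 0.0
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def fit_knn(matrix: RatingMatrix, k: int = 10, min_overlap: int = 2) -> KnnModel:
    """Compute pairwise user Pearson similarities over co-rated messages."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(matrix.users) < 2:
        raise ValueError("kNN needs at least 2 users")
    dense = matrix.to_dense()
    n = dense.shape[0]
    sim = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            both = ~np.isnan(dense[a]) & ~np.isnan(dense[b])
            if both.sum() >= min_overlap:
                s = _pearson(dense[a][both], dense[b][both])
            else:
                s = 0.0
            sim[a, b] = sim[b, a] = s
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows/cols
        user_means = np.nanmean(dense, axis=1)
        item_means = np.nanmean(dense, axis=0)
    user_means = np.where(np.isnan(user_means), matrix.global_mean(), user_means)
    return KnnModel(
        k=k,
        min_overlap=min_overlap,
        user_ids=list(matrix.users),
        item_ids=list(matrix.items),
        similarity=sim,
        user_means=user_means,
        dense=dense,
        item_means=item_means,
        global_mean=matrix.global_mean(),
    )


def _knn_combine(
    model: KnnModel,
    sims: np.ndarray,
    own_mean: float,
    item_idx: int,
) -> float:
    """Mean-centred weighted prediction over the k most similar raters."""
    rated = ~np.isnan(model.dense[:, item_idx])
    candidates = np.flatnonzero(rated & (sims != 0.0))
    if candidates.size == 0:
        im = model.item_means[item_idx]
        return _clip(model.global_mean if np.isnan(im) else float(im))
    order = candidates[np.argsort(-np.abs(sims[candidates]), kind="stable")]
    top = order[: model.k]
    w = sims[top]
    centred = model.dense[top, item_idx] - model.user_means[top]
    denom = np.abs(w).sum()
    if denom == 0.0:
        im = model.item_means[item_idx]
        return _clip(model.global_mean if np.isnan(im) else im)
    return _clip(own_mean + float((w * centred).sum() / denom))


def predict_knn(model: KnnModel, user: str, item: str) -> Prediction:
    """Predict one cell for a user the model was trained on.

    Falls back to the item mean (then the global mean) when no neighbour
    with nonzero similarity rated the item.
    """
    if user not in model.user_ids:
        raise KeyError(f"unknown user {user!r}")
    if item not in model.item_ids:
        raise KeyError(f"unknown message {item!r}")
    ui = model.user_ids.index(user)
    ii = model.item_ids.index(item)
    sims = model.similarity[ui].copy()
    sims[ui] = 0.0  # never one's own neighbour
    value = _knn_combine(model, sims, float(model.user_means[ui]), ii)
    return Prediction(user, item, value)


def predict_knn_from_ratings(
    model: KnnModel, ratings: Mapping[str, float], item: str
) -> float:
    """Cold-start kNN: similarity of an unseen user computed on the fly."""
    if item not in model.item_ids:
        raise KeyError(f"unknown message {item!r}")
    ii = model.item_ids.index(item)
    if not ratings:
        im = model.item_means[ii]
        return _clip(model.global_mean if np.isnan(im) else float(im))
    vec = np.full(len(model.item_ids), np.nan)
    for mid, v in ratings.items():
        vec[model.item_ids.index(mid)] = v
    own_mean = float(np.nanmean(vec))
    sims = np.zeros(len(model.user_ids))
    for u in range(len(model.user_ids)):
        both = ~np.isnan(vec) & ~np.isnan(model.dense[u])
        if both.sum() >= model.min_overlap:
            sims[u] = _pearson(vec[both], model.dense[u][both])
    return _knn_combine(model, sims, own_mean, ii)


# ---------------------------------------------------------------------------
# Factor models (PMF / BPMF)
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSample:
    """One retained Gibbs draw: factor matrices plus the user-side
    hyperparameters needed for cold-start conditional inference."""

    user_factors: np.ndarray  # N x D
    item_factors: np.ndarray  # M x D
    mu_user: np.ndarray  # D
    lambda_user: np.ndarray  # D x D precision


@dataclass
class FactorModel:
    """Latent-factor model; point estimates for PMF, draws for BPMF.

    When ``center`` is true the model factorises ratings minus the train
    global mean and adds it back at prediction time, so heavy shrinkage
    pulls predictions toward the mean rather than toward zero.
    """

    kind: str  # "pmf" | "bpmf"
    rank: int
    user_ids: list[str]
    item_ids: list[str]
    user_factors: np.ndarray  # N x D (posterior mean for BPMF)
    item_factors: np.ndarray  # M x D
    global_mean: float
    center: bool = True
    lambda_u: float = 0.0
    lambda_v: float = 0.0
    alpha: float = 2.0  # BPMF observation precision
    posterior_samples: list[PosteriorSample] = field(default_factory=list)
    objective_history: list[float] = field(default_factory=list)
    converged: bool = True
    seed: Optional[int] = None

    @property
    def offset(self) -> float:
        return self.global_mean if self.center else 0.0

    def item_checksum(self) -> str:
        """Digest of all non-user parameters; cold-start inference must
        never change it."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.item_factors).tobytes())
        for s in self.posterior_samples:
            h.update(np.ascontiguousarray(s.item_factors).tobytes())
            h.update(np.ascontiguousarray(s.mu_user).tobytes())
            h.update(np.ascontiguousarray(s.lambda_user).tobytes())
        h.update(np.float64(self.global_mean).tobytes())
        return h.hexdigest()


def fit_pmf(
    matrix: RatingMatrix,
    D: int = 8,
    lambda_u: float = 0.05,
    lambda_v: float = 0.05,
    n_iter: int = 100,
    seed: int = 0,
    center: bool = True,
    tol: float = 1e-6,
) -> FactorModel:
    """MAP probabilistic matrix factorization via alternating least squares.

    Minimises ``sum (r - u.v)^2 + lambda_u ||U||^2 + lambda_v ||V||^2``
    over the observed cells. Each half-sweep solves an exact ridge
    problem, so the objective is non-increasing; a model that has not
    reached ``tol`` relative improvement within ``n_iter`` sweeps is
    returned with ``converged=False`` (never silently).
    """
    if D < 1:
        raise ValueError("rank D must be >= 1")
    if lambda_u <= 0 or lambda_v <= 0:
        raise ValueError("regularizers must be > 0")
    rng = np.random.default_rng(seed)
    dense = matrix.to_dense()
    mu = matrix.global_mean() if center else 0.0
    R = dense - (matrix.global_mean() if center else 0.0)
    obs = ~np.isnan(dense)
    n, m = R.shape
    U = rng.normal(0.0, 0.1, (n, D))
    V = rng.normal(0.0, 0.1, (m, D))

    def objective() -> float:
        err = np.where(obs, R - U @ V.T, 0.0)
        return float(
            (err**2).sum() + lambda_u * (U**2).sum() + lambda_v * (V**2).sum()
        )

    history = [objective()]
    converged = False
    eye = np.eye(D)
    for _ in range(n_iter):
        for i in range(n):
            j = obs[i]
            if not j.any():
                U[i] = 0.0
                continue
            Vi = V[j]
            U[i] = np.linalg.solve(Vi.T @ Vi + lambda_u * eye, Vi.T @ R[i, j])
        for jdx in range(m):
            i = obs[:, jdx]
            if not i.any():
                V[jdx] = 0.0
                continue
            Ui = U[i]
            V[jdx] = np.linalg.solve(Ui.T @ Ui + lambda_v * eye, Ui.T @ R[i, jdx])
        history.append(objective())
        if history[-2] - history[-1] <= tol * max(history[-2], 1e-12):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"PMF ALS did not converge within {n_iter} sweeps "
            f"(last relative improvement above {tol})",
            RuntimeWarning,
        )
    return FactorModel(
        kind="pmf",
        rank=D,
        user_ids=list(matrix.users),
        item_ids=list(matrix.items),
        user_factors=U,
        item_factors=V,
        global_mean=matrix.global_mean(),
        center=center,
        lambda_u=lambda_u,
        lambda_v=lambda_v,
        objective_history=history,
        converged=converged,
        seed=seed,
    )


def _sample_hyperparams(
    X: np.ndarray,
    rng: np.random.Generator,
    beta0: float,
    nu0: int,
    mu0: np.ndarray,
    W0_inv: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-Wishart posterior draw for one side's factor prior."""
    N, D = X.shape
    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)
    beta_n = beta0 + N
    nu_n = nu0 + N
    mu_n = (beta0 * mu0 + N * xbar) / beta_n
    diff = (xbar - mu0).reshape(-1, 1)
    W_n_inv = W0_inv + S + (beta0 * N / beta_n) * (diff @ diff.T)
    W_n = np.linalg.inv(W_n_inv)
    W_n = (W_n + W_n.T) / 2.0
    Lam = wishart.rvs(df=nu_n, scale=W_n, random_state=rng)
    Lam = np.atleast_2d(Lam)
    cov_mu = np.linalg.inv(beta_n * Lam)
    mu = rng.multivariate_normal(mu_n, (cov_mu + cov_mu.T) / 2.0)
    return mu, Lam


def _sample_factors(
    R: np.ndarray,
    obs: np.ndarray,
    other: np.ndarray,
    mu: np.ndarray,
    Lam: np.ndarray,
    alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample each row factor from its Gaussian conditional.

    A row with zero observed ratings is drawn from the prior N(mu, Lam^-1)
    — deliberately not an error: the live system must always be able to
    score a message for a silent user.
    """
    n, D = R.shape[0], other.shape[1]
    out = np.empty((n, D))
    prior_term = Lam @ mu
    for i in range(n):
        j = obs[i]
        if j.any():
            Oj = other[j]
            prec = Lam + alpha * (Oj.T @ Oj)
            mean = np.linalg.solve(prec, prior_term + alpha * (Oj.T @ R[i, j]))
        else:
            prec = Lam
            mean = mu
        cov = np.linalg.inv(prec)
        out[i] = rng.multivariate_normal(mean, (cov + cov.T) / 2.0)
    return out


def fit_bpmf(
    matrix: RatingMatrix,
    D: int = 8,
    n_burn: int = 100,
    n_samples: int = 200,
    seed: int = 0,
    alpha: float = 2.0,
    center: bool = True,
    beta0: float = 2.0,
) -> FactorModel:
    """Bayesian PMF by Gibbs sampling with Gaussian-Wishart hyperpriors.

    Hyperprior: mu0 = 0, beta0 = 2, nu0 = D, W0 = I on both the user and
    item factor priors; observation noise precision ``alpha`` is fixed.
    After ``n_burn`` warm-up sweeps, ``n_samples`` draws of the factor
    matrices (plus user-side hyperparameters, for later cold-start
    inference) are retained. Predictions average u·v over the draws.
    """
    if D < 1:
        raise ValueError("rank D must be >= 1")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    dense = matrix.to_dense()
    gmean = matrix.global_mean()
    R = dense - (gmean if center else 0.0)
    obs = ~np.isnan(dense)
    Rz = np.where(obs, R, 0.0)
    n, m = R.shape
    mu0 = np.zeros(D)
    nu0 = D
    W0_inv = np.eye(D)
    # warm start from a short ALS run stabilises early sweeps
    U = rng.normal(0.0, 0.1, (n, D))
    V = rng.normal(0.0, 0.1, (m, D))
    samples: list[PosteriorSample] = []
    for sweep in range(n_burn + n_samples):
        mu_u, lam_u = _sample_hyperparams(U, rng, beta0, nu0, mu0, W0_inv)
        mu_v, lam_v = _sample_hyperparams(V, rng, beta0, nu0, mu0, W0_inv)
        U = _sample_factors(Rz, obs, V, mu_u, lam_u, alpha, rng)
        V = _sample_factors(Rz.T, obs.T, U, mu_v, lam_v, alpha, rng)
        if sweep >= n_burn:
            samples.append(
                PosteriorSample(
                    user_factors=U.copy(),
                    item_factors=V.copy(),
                    mu_user=mu_u.copy(),
                    lambda_user=lam_u.copy(),
                )
            )
    U_mean = np.mean([s.user_factors for s in samples], axis=0)
    V_mean = np.mean([s.item_factors for s in samples], axis=0)
    return FactorModel(
        kind="bpmf",
        rank=D,
        user_ids=list(matrix.users),
        item_ids=list(matrix.items),
        user_factors=U_mean,
        item_factors=V_mean,
        global_mean=gmean,
        center=center,
        alpha=alpha,
        posterior_samples=samples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Cold-start inference and prediction
# ---------------------------------------------------------------------------


@dataclass
class ColdUserFactor:
    """A new user's inferred factor under frozen non-user parameters.

    ``draws`` holds one factor per retained posterior sample for BPMF;
    for PMF it holds the single ridge solution. ``from_prior`` flags the
    empty-rating fallback (prior-mean factor)."""

    kind: str
    draws: np.ndarray  # S x D (S = 1 for PMF)
    from_prior: bool = False


def infer_user_factors(
    model: FactorModel,
    new_user_ratings: Mapping[str, float],
    seed: int = 0,
) -> ColdUserFactor:
    """Estimate a new user's latent factor from a few of their ratings.

    Item factors and hyperparameters are read, never written — the
    "strong generalization" contract. PMF: exact ridge solve against the
    frozen item factors. BPMF: one conditional Gibbs draw of the user
    factor per retained posterior sample.

    An empty rating set returns the prior-mean factor (zero vector, i.e.
    predictions collapse to the global mean) with a warning.
    """
    if not new_user_ratings:
        warnings.warn(
            "no ratings supplied; returning prior-mean user factor",
            RuntimeWarning,
        )
        n_draws = max(1, len(model.posterior_samples))
        return ColdUserFactor(
            kind=model.kind,
            draws=np.zeros((n_draws, model.rank)),
            from_prior=True,
        )
    unknown = [m for m in new_user_ratings if m not in model.item_ids]
    if unknown:
        raise KeyError(f"unknown message id(s) {unknown}")
    idx = np.array([model.item_ids.index(m) for m in new_user_ratings])
    r = np.array([float(v) for v in new_user_ratings.values()]) - model.offset
    if model.kind == "pmf":
        Vr = model.item_factors[idx]
        lam = model.lambda_u if model.lambda_u > 0 else 1e-8
        u = np.linalg.solve(Vr.T @ Vr + lam * np.eye(model.rank), Vr.T @ r)
        return ColdUserFactor(kind="pmf", draws=u.reshape(1, -1))
    if model.kind == "bpmf":
        rng = np.random.default_rng(seed)
        draws = np.empty((len(model.posterior_samples), model.rank))
        for s_i, s in enumerate(model.posterior_samples):
            Vr = s.item_factors[idx]
            prec = s.lambda_user + model.alpha * (Vr.T @ Vr)
            mean = np.linalg.solve(
                prec, s.lambda_user @ s.mu_user + model.alpha * (Vr.T @ r)
            )
            cov = np.linalg.inv(prec)
            draws[s_i] = rng.multivariate_normal(mean, (cov + cov.T) / 2.0)
        return ColdUserFactor(kind="bpmf", draws=draws)
    raise ValueError(f"unknown model kind {model.kind!r}")


def score_candidates(
    model: FactorModel, factor: ColdUserFactor, candidate_ids: Sequence[str]
) -> np.ndarray:
    """Predicted ratings (clipped) for many items at once.

    BPMF averages ``u_s . v_s`` over retained draws, pairing each user
    factor draw with the item factors of the same Gibbs sweep.
    """
    idx = []
    for mid in candidate_ids:
        if mid not in model.item_ids:
            raise KeyError(f"unknown message {mid!r}")
        idx.append(model.item_ids.index(mid))
    idx = np.asarray(idx, dtype=int)
    if model.kind == "bpmf" and not factor.from_prior and model.posterior_samples:
        V = np.stack([s.item_factors[idx] for s in model.posterior_samples])  # S x m x D
        raw = np.einsum("sd,smd->m", factor.draws, V) / len(model.posterior_samples)
    else:
        raw = model.item_factors[idx] @ np.mean(factor.draws, axis=0)
    return np.clip(raw + model.offset, RATING_MIN, RATING_MAX)


def predict_from_factor(
    model: FactorModel, factor: ColdUserFactor, item: str
) -> float:
    """Predicted rating for a cold-start user factor, clipped to [1, 5]."""
    return float(score_candidates(model, factor, [item])[0])


def predict(model: FactorModel, user: str, item: str) -> Prediction:
    """Predict one cell for a user seen at fit time.

    BPMF: the mean of u·v over posterior draws; PMF: the MAP dot product.
    """
    if user not in model.user_ids:
        raise KeyError(f"unknown user {user!r}")
    if item not in model.item_ids:
        raise KeyError(f"unknown message {item!r}")
    i = model.user_ids.index(user)
    j = model.item_ids.index(item)
    if model.kind == "bpmf":
        raw = float(
            np.mean(
                [s.user_factors[i] @ s.item_factors[j] for s in model.posterior_samples]
            )
        )
    else:
        raw = float(model.user_factors[i] @ model.item_factors[j])
    return Prediction(user, item, _clip(raw + model.offset))


def rank_messages(
    model: FactorModel | KnnModel,
    user: str | ColdUserFactor | Mapping[str, float],
    candidate_ids: Sequence[str],
) -> list[tuple[str, float]]:
    """Order candidate messages by predicted rating, best first.

    Ties are broken by ascending message id so a fixed model yields a
    deterministic total order across runs. ``user`` may be a trained
    user's id, a :class:`ColdUserFactor`, or (for kNN) a raw rating dict.
    """
    if isinstance(user, ColdUserFactor) and not isinstance(model, KnnModel):
        values = score_candidates(model, user, candidate_ids)
        scored = list(zip(candidate_ids, (float(v) for v in values)))
    else:
        scored = []
        for mid in candidate_ids:
            if isinstance(model, KnnModel):
                if isinstance(user, str):
                    v = predict_knn(model, user, mid).value
                else:
                    v = predict_knn_from_ratings(model, dict(user), mid)
            else:
                v = predict(model, str(user), mid).value
            scored.append((mid, v))
    return sorted(scored, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


def save_model(model: FactorModel, path: str | Path) -> None:
    """Serialize a factor model to JSON, posterior draws included, so a
    reload reproduces predictions bit-for-bit."""
    payload = {
        "kind": model.kind,
        "rank": model.rank,
        "user_ids": model.user_ids,
        "item_ids": model.item_ids,
        "user_factors": model.user_factors.tolist(),
        "item_factors": model.item_factors.tolist(),
        "global_mean": model.global_mean,
        "center": model.center,
        "lambda_u": model.lambda_u,
        "lambda_v": model.lambda_v,
        "alpha": model.alpha,
        "converged": model.converged,
        "seed": model.seed,
        "posterior_samples": [
            {
                "user_factors": s.user_factors.tolist(),
                "item_factors": s.item_factors.tolist(),
                "mu_user": s.mu_user.tolist(),
                "lambda_user": s.lambda_user.tolist(),
            }
            for s in model.posterior_samples
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> FactorModel:
    d = json.loads(Path(path).read_text())
    return FactorModel(
        kind=d["kind"],
        rank=d["rank"],
        user_ids=d["user_ids"],
        item_ids=d["item_ids"],
        user_factors=np.asarray(d["user_factors"], dtype=float),
        item_factors=np.asarray(d["item_factors"], dtype=float),
        global_mean=d["global_mean"],
        center=d["center"],
        lambda_u=d["lambda_u"],
        lambda_v=d["lambda_v"],
        alpha=d["alpha"],
        converged=d["converged"],
        seed=d["seed"],
        posterior_samples=[
            PosteriorSample(
                user_factors=np.asarray(s["user_factors"], dtype=float),
                item_factors=np.asarray(s["item_factors"], dtype=float),
                mu_user=np.asarray(s["mu_user"], dtype=float),
                lambda_user=np.asarray(s["lambda_user"], dtype=float),
            )
            for s in d["posterior_samples"]
        ],
    )
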