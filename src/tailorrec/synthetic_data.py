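"""Synthetic two-group messaging-trial cohorts with known ground truth.

The generator emulates the shape of a tailored-messaging cessation trial:
two groups of users (an intervention group and a comparison group), a
bank of 261 expert/peer messages, one message per user per day for 30
days inside a 65-day window, sparse optional 1-5 replies, website-visit
counts, and a 30-day cessation outcome whose group difference is partly
transmitted through each user's mean daily rating.

Generative model (all reproducible from one seed):

* latent preferences — user factor ``u_i`` and item factor ``v_j`` of a
  chosen rank; the continuous reply is
  ``base + delta * group + u_i . v_j + eps``, ``eps ~ N(0, sigma)``,
  rounded to the Likert grid and then clipped to [1, 5];
* engagement — each sent message is rated with a per-group daily
  completion probability; unrated sends stay in the event stream with a
  missing value;
* visits ~ Poisson with a per-group rate;
* cessation ~ Bernoulli(expit(alpha + beta * group + gamma * mean
  rating)): ``beta`` is the direct group effect on the log-odds, ``gamma``
  routes the effect through the mediator.

:func:`true_mediation` computes the cohort's *true* mediation decomposition
by brute-force potential-outcome simulation under this known model — the
oracle against which the estimator in :mod:`tailorrec.trial_stats` is
validated. Ground truth is written to a separate file (``truth.json``) so
pipeline code cannot accidentally read it.

A ``preference_structure="item_cluster"`` switch replaces the latent-factor
signal with cluster-level preferences (each message belongs to one content
cluster, each user has one preference per cluster) — a regime the factor
models are *mis*specified for, used in robustness tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import expit

from .data_model import (
    Message,
    RatingEvent,
    RatingMatrix,
    TrialRecord,
    UserProfile,
    READINESS_STAGES,
    write_message_bank,
    write_profiles,
    write_ratings,
    write_trial,
)

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort", "true_mediation", "write_cohort"]

_TAG_VOCAB = ("reasons-to-quit", "tips-strategies", "nrt", "distraction-substitution")


@dataclass
class CohortSpec:
    """Parameters of the synthetic trial.

    Defaults mirror the study conditions the toolkit targets: group sizes
    55 (intervention) + 64 (comparison), a 261-message bank, up to 30
    messages within 65 days, mean replies in the low-4s with a ~0.2-point
    group gap, higher rating completion and website engagement in the
    intervention group, and outcome parameters placing roughly 40% of the
    group effect on cessation on the mediated path. ``outcome_beta`` is
    the direct group effect on the cessation log-odds; ``outcome_gamma``
    the mediator (mean rating) effect.
    """

    n_per_group: tuple[int, int] = (55, 64)  # (intervention, comparison)
    group_labels: tuple[str, str] = ("african_american", "white")
    n_messages: int = 261
    latent_rank: int = 3
    base_rating: float = 4.15
    group_rating_shift: float = 0.20  # delta: additive gap for the intervention group
    factor_scale: float = 0.35  # sd of the u.v preference signal
    rating_noise: float = 0.60  # sigma of eps
    engagement: tuple[float, float] = (0.92, 0.72)  # P(rate | sent) per group
    visit_rate: tuple[float, float] = (5.5, 1.5)  # Poisson means
    outcome_alpha: float = -8.59
    outcome_beta: float = 0.52
    outcome_gamma: float = 1.97
    impact_means: tuple[tuple[float, ...], tuple[float, ...]] = (
        (4.2, 4.2, 4.2, 4.2, 3.2, 4.2, 4.2),  # intervention; NRT item depressed
        (3.9, 3.9, 3.9, 3.9, 4.0, 3.9, 3.9),
    )
    horizon_messages: int = 30
    horizon_days: int = 65
    preference_structure: str = "latent"  # or "item_cluster"
    n_clusters: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_messages < self.horizon_messages:
            raise ValueError(
                f"bank of {self.n_messages} messages cannot cover a "
                f"{self.horizon_messages}-message horizon"
            )
        if self.rating_noise <= 0:
            raise ValueError("rating_noise must be > 0")
        for p in self.engagement:
            if not 0 <= p <= 1:
                raise ValueError("engagement probabilities must be in [0, 1]")
        if self.preference_structure not in ("latent", "item_cluster"):
            raise ValueError(f"unknown preference_structure {self.preference_structure!r}")


@dataclass
class SyntheticCohort:
    """Observable tables plus ground truth (kept separate on disk)."""

    spec: CohortSpec
    bank: list[Message]
    profiles: list[UserProfile]
    events: list[RatingEvent]
    trial: list[TrialRecord]
    truth: dict = field(default_factory=dict)

    def rating_matrix(self) -> RatingMatrix:
        return RatingMatrix.from_events(
            self.events,
            users=[p.user_id for p in self.profiles],
            items=[m.message_id for m in self.bank],
        )


def _likert(x: np.ndarray) -> np.ndarray:
    """Continuous reply -> Likert grid: round first, then clip to [1, 5]."""
    return np.clip(np.rint(x), 1, 5)


def _make_bank(spec: CohortSpec, rng: np.random.Generator) -> list[Message]:
    bank = []
    sources = rng.permutation(
        ["expert"] * (spec.n_messages // 2) + ["peer"] * (spec.n_messages - spec.n_messages // 2)
    )
    for j in range(spec.n_messages):
        tag = _TAG_VOCAB[j % len(_TAG_VOCAB)]
        bank.append(
            Message(
                message_id=f"m{j:03d}",
                text=f"[synthetic] motivational message {j} ({tag})",
                source=str(sources[j]),
                tags=frozenset({tag}),
            )
        )
    return bank


#: Baseline marginals per group (intervention, comparison): probability of
#: the listed level, used only to make profiles realistic-looking.
_PROFILE_MARGINALS = {
    "gender_female": (0.60, 0.63),
    "education_advanced": (0.22, 0.20),
    "ethnicity_hispanic": (0.05, 0.03),
    "allow_smoking_home": (0.65, 0.37),
    "visited_cessation_site": (0.13, 0.19),
    "past_year_quit_attempt": (0.45, 0.44),
    "actively_quitting": (0.20, 0.19),
}
_AGE_PROBS = ((0.31, 0.25, 0.44), (0.33, 0.27, 0.40))
_READINESS_PROBS = (0.35, 0.40, 0.10, 0.05, 0.10)


def _make_profiles(spec: CohortSpec, rng: np.random.Generator) -> list[UserProfile]:
    profiles = []
    for g, (label, n) in enumerate(zip(spec.group_labels, spec.n_per_group)):
        gi = g  # 0 = intervention, 1 = comparison in the marginals
        for i in range(n):
            age = ("19-34", "35-44", "45+")[
                rng.choice(3, p=np.array(_AGE_PROBS[gi]) / sum(_AGE_PROBS[gi]))
            ]
            profiles.append(
                UserProfile(
                    user_id=f"{label[:2]}{i:03d}",
                    group=label,
                    gender="female"
                    if rng.random() < _PROFILE_MARGINALS["gender_female"][gi]
                    else "male",
                    age_band=age,
                    education="advanced_degree"
                    if rng.random() < _PROFILE_MARGINALS["education_advanced"][gi]
                    else "other",
                    ethnicity="hispanic"
                    if rng.random() < _PROFILE_MARGINALS["ethnicity_hispanic"][gi]
                    else "not_hispanic",
                    allow_smoking_home=bool(
                        rng.random() < _PROFILE_MARGINALS["allow_smoking_home"][gi]
                    ),
                    visited_cessation_site=bool(
                        rng.random() < _PROFILE_MARGINALS["visited_cessation_site"][gi]
                    ),
                    past_year_quit_attempt=bool(
                        rng.random() < _PROFILE_MARGINALS["past_year_quit_attempt"][gi]
                    ),
                    smoking_status="actively_quitting"
                    if rng.random() < _PROFILE_MARGINALS["actively_quitting"][gi]
                    else "not_actively_quitting",
                    readiness=READINESS_STAGES[rng.choice(5, p=_READINESS_PROBS)],
                )
            )
    return profiles


def _signal_factors(
    spec: CohortSpec, n_users: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Latent structure: (user_factors, item_factors) such that the
    preference signal is ``user_factors @ item_factors.T``."""
    if spec.preference_structure == "latent":
        D = spec.latent_rank
        s = np.sqrt(spec.factor_scale / np.sqrt(D))
        return rng.normal(0, s, (n_users, D)), rng.normal(0, s, (spec.n_messages, D))
    # item-cluster regime: v_j = one-hot(cluster_j), u_i = per-cluster preference
    clusters = rng.integers(0, spec.n_clusters, spec.n_messages)
    V = np.eye(spec.n_clusters)[clusters]
    U = rng.normal(0, spec.factor_scale, (n_users, spec.n_clusters))
    return U, V


def generate_cohort(
    spec: CohortSpec,
    include_truth: bool = True,
    truth_n_mc: int = 200_000,
) -> SyntheticCohort:
    """Draw one full cohort from the generative model.

    ``include_truth`` also runs the potential-outcome oracle
    (:func:`true_mediation`) and stores its output alongside the latent
    factors in ``cohort.truth``.
    """
    rng = np.random.default_rng(spec.seed)
    bank = _make_bank(spec, rng)
    profiles = _make_profiles(spec, rng)
    n_users = len(profiles)
    treated = np.array([p.group == spec.group_labels[0] for p in profiles], dtype=float)
    U, V = _signal_factors(spec, n_users, rng)

    events: list[RatingEvent] = []
    observed_mean = np.full(n_users, np.nan)
    for i, prof in enumerate(profiles):
        g = 0 if treated[i] else 1
        sent = rng.permutation(spec.n_messages)[: spec.horizon_messages]
        rated_mask = rng.random(spec.horizon_messages) < spec.engagement[g]
        mu = (
            spec.base_rating
            + spec.group_rating_shift * treated[i]
            + U[i] @ V[sent].T
        )
        vals = _likert(mu + rng.normal(0, spec.rating_noise, spec.horizon_messages))
        got: list[float] = []
        for day, (j, rated) in enumerate(zip(sent, rated_mask), start=1):
            value = int(vals[day - 1]) if rated else None
            events.append(RatingEvent(prof.user_id, f"m{j:03d}", day, value))
            if rated:
                got.append(vals[day - 1])
        if got:
            observed_mean[i] = float(np.mean(got))

    # mediator for the outcome model: the user's observed mean rating;
    # a (vanishingly rare) never-rater falls back to their expected level
    mediator = np.where(
        np.isnan(observed_mean),
        spec.base_rating + spec.group_rating_shift * treated,
        observed_mean,
    )
    p_quit = expit(spec.outcome_alpha + spec.outcome_beta * treated + spec.outcome_gamma * mediator)
    quit_flags = rng.random(n_users) < p_quit

    trial: list[TrialRecord] = []
    for i, prof in enumerate(profiles):
        g = 0 if treated[i] else 1
        visits = int(rng.poisson(spec.visit_rate[g]))
        impact = tuple(
            int(v)
            for v in _likert(np.array(spec.impact_means[g]) + rng.normal(0, 1.0, 7))
        )
        trial.append(
            TrialRecord(
                user_id=prof.user_id,
                group=prof.group,
                website_visits=visits,
                impact_items=impact,
                quit_30day=bool(quit_flags[i]),
            )
        )

    truth: dict = {
        "user_factors": U.tolist(),
        "item_factors": V.tolist(),
        "treated": treated.tolist(),
        "observed_mean_rating": [None if np.isnan(v) else float(v) for v in observed_mean],
        "quit_probability": p_quit.tolist(),
    }
    if include_truth:
        truth["mediation"] = true_mediation(spec, n_mc=truth_n_mc)
    return SyntheticCohort(
        spec=spec, bank=bank, profiles=profiles, events=events, trial=trial, truth=truth
    )


def true_mediation(spec: CohortSpec, n_mc: int = 200_000, seed: Optional[int] = None) -> dict:
    """Ground-truth mediation decomposition by brute-force potential-outcome
    simulation under the spec's generative model.

    For each of ``n_mc`` simulated users, the potential mediator value
    ``m(g)`` (mean observed rating had the user been in group ``g``) is
    computed with shared latent factors, noise and engagement draws across
    the two arms — only the group terms differ. ACME averages the
    probability effect of switching the mediator's potential value while
    holding group, over both arms; the total effect switches both.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003 if seed is None else seed)
    H = spec.horizon_messages

    def prob(t: float, m: np.ndarray) -> np.ndarray:
        return expit(spec.outcome_alpha + spec.outcome_beta * t + spec.outcome_gamma * m)

    # accumulate in chunks so n_mc = 1e6 stays memory-bounded
    sums = np.zeros(9)  # delta0, delta1, zeta0, zeta1, total, m0, m1, p0, p1
    chunk = 100_000
    done = 0
    while done < n_mc:
        n = min(chunk, n_mc - done)
        if spec.preference_structure == "latent":
            D = spec.latent_rank
            s = np.sqrt(spec.factor_scale / np.sqrt(D))
            Umc = rng.normal(0, s, (n, D))
            Vmc = rng.normal(0, s, (n, H, D))
            signal = np.einsum("id,ihd->ih", Umc, Vmc)
        else:
            pref = rng.normal(0, spec.factor_scale, (n, spec.n_clusters))
            cl = rng.integers(0, spec.n_clusters, (n, H))
            signal = np.take_along_axis(pref, cl, axis=1)
        eps = rng.normal(0, spec.rating_noise, (n, H))
        u_eng = rng.random((n, H))

        def potential_mediator(g: int) -> np.ndarray:
            arm = 0 if g == 1 else 1  # group 1 = intervention (index 0 in tuples)
            vals = _likert(spec.base_rating + spec.group_rating_shift * g + signal + eps)
            mask = u_eng < spec.engagement[arm]
            cnt = mask.sum(axis=1)
            return np.where(
                cnt > 0,
                (vals * mask).sum(axis=1) / np.maximum(cnt, 1),
                spec.base_rating + spec.group_rating_shift * g,
            )

        m0, m1 = potential_mediator(0), potential_mediator(1)
        sums += np.array(
            [
                (prob(0, m1) - prob(0, m0)).sum(),
                (prob(1, m1) - prob(1, m0)).sum(),
                (prob(1, m0) - prob(0, m0)).sum(),
                (prob(1, m1) - prob(0, m1)).sum(),
                (prob(1, m1) - prob(0, m0)).sum(),
                m0.sum(),
                m1.sum(),
                prob(0, m0).sum(),
                prob(1, m1).sum(),
            ]
        )
        done += n
    delta0, delta1, zeta0, zeta1, total_s, m0_s, m1_s, p0_s, p1_s = sums / n_mc
    acme = float(0.5 * (delta0 + delta1))
    ade = float(0.5 * (zeta0 + zeta1))
    total = float(total_s)
    return {
        "acme": acme,
        "ade": ade,
        "total": total,
        "percent_mediated": 100.0 * acme / total if total else float("nan"),
        "mediator_means": {"treated": float(m1_s), "control": float(m0_s)},
        "quit_probability": {"treated": float(p1_s), "control": float(p0_s)},
        "n_mc": n_mc,
    }


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Emit messages.json, profiles.csv, ratings.csv, trial.csv and
    truth.json; byte-identical across runs with the same spec."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_message_bank(cohort.bank, out / "messages.json")
    write_profiles(cohort.profiles, out / "profiles.csv")
    write_ratings(cohort.events, out / "ratings.csv")
    write_trial(cohort.trial, out / "trial.csv")
    payload = dict(cohort.truth)
    payload["spec"] = asdict(cohort.spec)
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
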