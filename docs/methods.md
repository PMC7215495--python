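# Methods

This note records the models implemented in `tailorrec`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions a maintainer would need.

## Rating models

The observable object is a sparse users × messages matrix of 1–5 Likert
replies; unobserved cells are absent, never zero (zero is off-scale and
would corrupt every mean).

**user-kNN.** Pearson correlation between users over co-rated messages,
set to 0 when the overlap is below `min_overlap` (default 2) or a vector
is constant. Prediction: the target user's mean plus the
absolute-weight-normalised sum of the k most similar raters' mean-centred
ratings of the item; fallback to the item mean, then the global mean. The
classical user-based formulation; k defaults to 10.

**PMF.** MAP estimate of `Σ (r − u·v)² + λ_u‖U‖² + λ_v‖V‖²` by
alternating least squares rather than SGD: each half-sweep is an exact
ridge solve, so the objective is provably non-increasing and the fit is
deterministic given the init seed — both directly testable. Defaults
D = 8, λ = 0.05, up to 100 sweeps, relative tolerance 1e-6; a fit that
has not met the tolerance returns `converged=False` and warns.
`center=True` (default) factorises ratings minus the train global mean
and adds it back at prediction, so heavy shrinkage pulls predictions to
the mean; `center=False` factorises raw ratings, which is the mode in
which an exactly rank-1 matrix is recovered exactly at D = 1 (a centred
rank-1 matrix generally has a rank-2 residual, so both behaviours cannot
hold in one configuration — hence the switch).

**BPMF.** Gibbs sampling over user and item factor matrices with
Gaussian–Wishart hyperpriors (μ₀ = 0, β₀ = 2, ν₀ = D, W₀ = I) on each
side's factor prior, observation precision α fixed. Defaults D = 8,
100 burn-in sweeps, 200 retained draws; tests and the acceptance script
use smaller chains (25–50 burn-in, 30–100 draws) and smaller matrices so
the whole suite runs in minutes on one CPU — chain-length and
problem-size choices of this package, validated by the planted-factor
recoveries they achieve. α defaults to 2, appropriate for Likert noise
near unit scale; on low-noise planted data (σ = 0.25) the fits use
α = 1/σ² = 16 — α is a modelling choice that should match the reply
noise. A user or item with no ratings is drawn from its prior: the live
system must always be able to score a message, so this is a documented
behaviour, not an error.

**Cold start.** `infer_user_factors` never touches item factors or
hyperparameters (checksum-asserted). PMF: one ridge solve against the
frozen item factors. BPMF: per retained draw, one conditional Gaussian
draw of the user factor given that draw's item factors and user-side
hyperparameters. An empty rating set returns the prior-mean (zero)
factor with a warning, which collapses predictions to the global mean.

All predictions are clipped to [1, 5]; candidate rankings break ties by
ascending message id so a fixed model gives one deterministic total
order.

## Evaluation protocol

Strong generalization: models are fit on train users only; each test
user's parameters are inferred from nested support sets (5 ⊂ 10 ⊂ 16
ratings) and scored on exactly 4 held-back ratings. Users need ≥ 20
ratings (16 + 4) to be eligible as test users; others serve in every
training fold. 5 user folds; 3 validation partitions per fold, each
holding out 10% of every train user's ratings (the fraction is this
package's choice). Fold-level RMSE pools all test predictions in the
fold; τ-b and NDCG are computed per user on the 4-vectors and averaged
(τ-b of an all-tied vector is undefined and excluded).

NDCG uses exponential gain `2^rel − 1` and `log2(rank+1)` discount — the
most common convention; the metric's name alone does not pin one down.
Kendall's τ-b is the tie-corrected form `(C − D)/√((n₀−n₁)(n₀−n₂))`.

Grid search minimises mean validation RMSE; when a selected value sits at
an endpoint of its range the range is extended in that direction —
geometrically for scale parameters, arithmetically for counts — and the
search repeats, up to 3 extensions, after which an endpoint optimum is
returned flagged with a warning.

The leakage audit records every (fold, user, item) rating consumed in
fitting or inference and intersects it with the held-back test cells of
the same fold. The audit is fold-scoped on purpose: a user's test
ratings are banned in the fold where they are a test user, while the same
cells legitimately enter training in folds where they are a train user.

Model comparison: two-sided paired t over fold-level metric values,
Bonferroni-multiplied by the number of model pairs, capped at 1.
Zero-variance differences are degenerate: identical vectors report t = 0,
p = 1; a constant nonzero difference reports p as missing with a note.

## Scheduler

One message per active user per day: the highest-predicted unsent
message. Ratings are optional; a reply immediately re-runs user-factor
inference (one conditional solve, so per-rating updates are cheap and
maximise the feedback loop). Item factors stay frozen during scheduling,
mirroring the contract under which the models are evaluated; live item
retraining is a possible alternative deliberately not taken here. Hard
caps: 30 messages, 65 days, whichever first; the send-day cadence is
configurable (default consecutive days) and the caps hold for any skip
pattern.

## Trial statistics

- Daily rating = mean of the replies submitted by a group's members on a
  day; no-reply days are missing, never 0. Group comparison: two-sample
  t on the daily means, pooled-variance by default with Welch as an
  option. Two identical constant series are reported as t = 0, p = 1.
- Impact items dichotomize at ≥ 4 (agree/strongly agree); missing stays
  missing and drops out of denominators (complete-case throughout).
- 2×2 tables: Pearson chi-square without continuity correction (df = 1);
  a zero margin returns missing with a warning. Odds ratio: ad/bc with
  95% Wald CI; any zero cell triggers the Haldane–Anscombe +0.5
  correction, flagged.
- Trend across ordered categories: the Cochran–Armitage/Mantel-extension
  score statistic without the (N−1)/N factor, so k = 2 with scores (0, 1)
  reduces exactly to the Pearson chi-square.
- Logistic regression: statsmodels MLE with Wald CIs; complete separation
  and non-convergence raise named errors.

**Mediation.** Quasi-Bayesian potential-outcome algorithm: a linear model
for the mediator and a logistic model for the outcome; 1000 parameter
draws (default) from each fit's asymptotic normal distribution; potential
mediator values simulated with the linear model's estimated residual SD;
ACME, ADE and the total effect computed on the probability scale and
averaged over the two treatment arms, giving the exact identity
ACME + ADE = total under this convention; percentile CIs from the draws.
The mediator is the *per-user mean rating* — the only per-subject scalar
compatible with a subject-level outcome model; the day-level series is
the alternative reading, not taken. Percent mediated = 100·ACME/total; a
total-effect CI spanning 0 flags the percentage as unstable. Multi-cohort
summaries pool as 100·mean(ACME)/mean(total): per-cohort percent ratios
diverge whenever one cohort's total effect is near zero, while the pooled
form is stable and unbiased in simulation.

## Synthetic cohorts and calibration

The generator emulates the shape of the target trial: 55 + 64 users, 261
messages, one message per day for 30 days in a 65-day window, sparse
optional replies, Poisson website visits, Bernoulli cessation. Continuous
replies are `base + δ·group + uᵢ·vⱼ + ε`, rounded to the Likert grid and
then clipped (in that order — discrete replies first hit the grid, and
the scale ends at 5). Defaults, frozen after one calibration pass:
`base = 4.15`, group shift `δ = 0.20`, preference-signal SD 0.35, reply
noise σ = 0.60, rating-completion probabilities (0.92, 0.72), visit rates
(5.5, 1.5), and outcome parameters `α = −8.59, β = 0.52, γ = 1.97` on the
logit of cessation against group and mean rating. Under these values the
observed group rating means sit near 4.30/4.12, arm cessation
probabilities near 0.60/0.39, and the oracle-computed true mediated
fraction at 40% — the regime the toolkit's recovery tests target.

`true_mediation` computes the ground truth by brute force: for up to 10⁶
simulated users the potential mediator values under both arms share
latent factors, noise and engagement draws (only the group terms differ),
and effects are averaged exactly as the estimator averages them. Chunked
evaluation keeps memory flat; two independent 4·10⁵ runs agree to ±0.5
points. Ground truth is written to a separate `truth.json` so pipeline
code cannot read it by accident.

A `preference_structure="item_cluster"` switch replaces the latent-factor
signal with cluster-level preferences — a regime the factor models are
misspecified for — to separate estimator bugs from model misfit.

What the generator does **not** emulate: message text semantics, drift of
preferences over time, dependence of engagement on message content, or
avoidance dynamics around specific content (e.g. NRT messages). Passing
tests therefore demonstrate the machinery's correctness and its
statistical behaviour under a known generative model, not effect sizes in
real cohorts.

**Personalization test bed.** At the trial-scale defaults the preference
signal (SD 0.35) against reply noise (SD 0.60, plus rounding) leaves a
user's factor statistically unidentifiable from 30 replies — cold-start
predictions correlate ~0.02 with truth — so no recommender could show a
late-versus-early improvement there. The scheduler's personalization
property is therefore tested in a clear-preference regime
(signal SD² scale 0.8, noise 0.45; prediction–truth correlation ≈ 0.5 at
30 ratings), where the mean true appeal of days 21–30 picks exceeds days
1–10 by ≈ 0.10 points across 100 daily-rating users. The property is a
statement about the feedback mechanism; trial-scale defaults are left
untouched.

## Known limitations

- BPMF keeps α fixed rather than learning the noise level; a mismatched
  α degrades accuracy (see the planted-data convention above).
- The kNN similarity matrix is O(n²) in users and computed densely —
  appropriate for cohort-scale data (hundreds of users), not for large
  registries.
- Mediation assumes no unmeasured treatment–mediator or mediator–outcome
  confounding and a correctly specified linear mediator model; the
  generator satisfies these by construction, real data need not.
- Checkpoints serialise posterior draws to JSON; for very long chains a
  binary format would be preferable.
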