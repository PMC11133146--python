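# Methods

This note documents the models implemented in `habitsim`, the synthetic
data-generating process, the numerical choices, and the design decisions
taken where the paradigm left the design open. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## The task model

The task is a free-operant instrumental paradigm: a participant may
"enter" at any moment, each entry costing 1 gold unit and yielding gold
(15 units) or a worthless rock. The engine (`task_engine`) implements:

- **Reinforcement schedule.** Each entry finds gold with probability 1/3
  (a VR-3 variable-ratio schedule). Two deterministic layers sit on top:
  the first daily entry is forced to a rock and the second to gold, and
  after six consecutive rocks the next entry is guaranteed gold. The
  forced pattern is layered *on top of* the random schedule (the forced
  draws do not consume random numbers), and the failure-streak counter
  persists across days — in practice the forced gold on ordinal 2 resets
  it every morning. A random-interval option (reward armed after an
  exponential waiting time, delivered on the next entry, mean 600 s by
  default) and an aversive-outcome flag are implemented as configurable
  alternatives.
- **Days and the warehouse.** Experiment days are delimited by a 05:00
  clock boundary; timestamps are timezone-naive seconds from experiment
  start (midnight before day 1). The warehouse empties at the start of
  each day. On manipulation days the fifth daily entry triggers the
  warehouse message — *full* (outcome devaluation: gold no longer
  credits) or *half full* (control: value retained) — and outcomes are
  masked from the third daily entry until the day ends. Masking hides
  outcomes but never alters them or their crediting. If the message is
  not confirmed it reappears on every subsequent entry; simulated agents
  confirm immediately, and the re-display path is exercised only in
  targeted tests. Entries *under manipulation* — the dependent variable —
  are those after the message entry on a manipulation day.
- **Groups.** Short training: 4 days, manipulations on days 2–4
  (control, devaluation, control). Extensive training: 11 days,
  manipulations on days 9–11. The extensive-parallel variant adds
  control manipulations on days 2–4.
- **Cave mini-task.** After each manipulation message the participant
  may press targets in a cave holding exactly 15 gold piles and 15
  rocks; every press costs 10 units and each pile credits 15 — only
  while the warehouse is valued. The three-press entry sequence is
  modelled as always completed (a `sequence_completed` flag exists but
  partial sequences are not generated or analysed).

## The synthetic participant

`agents` generates event streams with the three features the analyses
rely on: micro-session structure, heavy overdispersion, and graded
devaluation sensitivity.

- **Sessions.** Per day, the number of self-initiated sessions is
  Poisson (default mean 6.7, floored at 1), session onsets are uniform
  in a waking window (08:00–23:00), and entries per session follow a
  shifted negative binomial (mean 8, dispersion k = 2) with
  within-session gaps uniform on (10, 60) s — strictly below the 300 s
  sessionization threshold by construction. These per-session defaults
  are a modelling choice: only daily summary engagement (median ≈ 53
  entries/day, mean ≈ 122, SD ≈ 181 across participants) is documented
  for the reference population, so the session split was chosen as
  "roughly 7 bursts of roughly 8 entries" and calibrated to those daily
  statistics.
- **Heterogeneity.** In a cohort, each participant's session rate is
  multiplied by a median-preserving lognormal draw (σ = 1.284), chosen
  so the cohort's daily-count distribution has a mean/median ratio
  ≈ 2.3 matching the reference engagement figures. This heterogeneity —
  not within-day noise — is what produces variance/mean ratios far above
  1 in daily counts and motivates the negative-binomial models.
- **Devaluation sensitivity.** Habit strength is a thinning parameter
  `s ∈ [0, 1]`: each entry the agent would have committed after the
  devaluation message survives with probability 1 − s, so the expected
  post-manipulation count is (1 − s) times the matched valued-day
  expectation. Thinning (rather than truncation) keeps fractional habit
  strengths expressible; `s = 1` produces exactly zero post-devaluation
  entries and an adaptation index of 1. An analogous
  `control_sensitivity` (default 0) applies on control days. A
  compliance floor tops up days below the 5-entry minimum.
- **What is not modelled.** Circadian structure beyond the waking
  window, day-of-week effects, reactive changes in engagement after
  (un)rewarded entries, drop-out, and any cognitive model of entry
  timing. Passing tests therefore show the *analysis pipeline* behaves
  correctly on data with the assumed structure — not that human
  engagement follows this generative process.

## Behavioural measures

The adaptation index is
(√μ_valued − √devalued) / (√μ_valued + √devalued), with μ_valued the
mean of the post-manipulation counts on the control days flanking
devaluation. It is 1 when no devalued entries occur, 0 when devalued
responding equals valued responding, and is left undefined (an explicit
error, not a silent 0) when both terms are zero. Sessionization splits a
timestamp stream at inter-entry gaps ≥ 300 s (strict "< 300 s belongs to
the session" rule). Engagement indices exclude the devaluation day by
default, with a variant excluding all manipulation days as a robustness
check. Quartile splits of baseline engagement use linear-interpolation
sample quantiles with membership by ≤ Q1 / ≥ Q3, computed within each
training group by default; the baseline is the post-manipulation count
on the pre-devaluation control day, mirroring the dependent variable's
definition.

## Count models

The confirmatory model is
`entries ~ manipulation * group + (1 | participant)` with reference
levels control-pre and short training (nine fixed effects). Four
families are available:

| family  | conditional variance | extra parameter |
|---------|----------------------|-----------------|
| poisson | μ                    | —               |
| olre    | μ (plus a per-observation normal intercept) | σ_o |
| nb1     | μ(1 + α)             | α ≥ 0           |
| nb2     | μ + μ²/θ             | θ > 0           |

The participant intercept is integrated out by **adaptive Gauss–Hermite
quadrature** (15 nodes by default): the integrand's mode and curvature
are found per participant by damped Newton iterations, and the nodes are
recentred and rescaled there. OLRE adds a nested per-observation
quadrature of the same form. Optimization is bounded L-BFGS-B on
(β, log σ_b, log dispersion) with analytic gradients obtained from the
Fisher identity (the gradient of the marginal likelihood equals the
posterior expectation of the complete-data score, computable from the
same quadrature weights). Standard errors come from the observed
information (central-difference Hessian). The random-effect standard
deviation is bounded below at 1e-4; a solution pinned there is reported
with a boundary warning. NB1 and NB2 marginal likelihoods approach the
Poisson fit as their dispersion vanishes (nesting is covered by a test),
and the implementation is cross-checked against an independent R
reference fit on a frozen simulated dataset.

**Overdispersion diagnostic.** The dispersion ratio is the sum of
squared Pearson residuals over residual degrees of freedom
(n − fixed effects − variance parameters), with residuals computed at
the conditional means (empirical-Bayes participant modes) — matching the
convention of the standard mixed-model diagnostic tooling. With clusters
of size 3 this conditional ratio sits *below* 1 under equidispersion
(≈ 0.72 in the frozen test dataset, identical to the R reference); the
diagnostic's job is flagging order-of-magnitude overdispersion, which it
does.

**Model selection.** Leave-one-out cross-validation refits the model
without each held-out observation (warm-started at the full-data
estimates) and predicts it from the conditional mean at the
participant's re-estimated empirical-Bayes mode (for OLRE, times the
lognormal mean factor e^{σ_o²/2}). The family with the lowest mean
squared error wins. A leave-one-participant-out option predicts from the
marginal mean instead. Any fold that fails to fit flags the family and
excludes it with a warning.

**Interaction tests.** The overall group × manipulation test is a Wald
chi-square on the 4-coefficient interaction block; simple interactions
are per-coefficient Wald z tests, plus the devaluation-interaction
contrast between the two extensive groups; simple group effects on the
pre-devaluation day are the group main effects under treatment coding.

**Mixture clustering.** The adaptation index distribution is fit with
univariate Gaussian mixtures, k ∈ {1, 2}, by EM with 20 random
restarts, a 1e-4 variance floor and a 1e-8 tolerance; k is chosen by
BIC (= −2ℓ + (3k − 1) log n). Zero post-devaluation counts put an atom
of index values at exactly 1.0, onto which a mixture component can
collapse (the classic unbounded-likelihood degeneracy — the variance
floor turns it into a spuriously winning finite solution). Restarts
whose solution pins a variance at the floor are therefore rejected as
degenerate, and a k whose every restart degenerates drops out of the
BIC comparison. This mirrors how unfloored EM implementations fail on
such runs rather than report them.

**Rank-based regression.** Engagement analyses minimize Jaeckel's rank
dispersion D(β) = Σ a(R(e_i)) e_i with Wilcoxon scores
a(i) = √12 (i/(n+1) − ½) (Nelder–Mead from the least-squares start; the
objective is convex). The intercept is the median residual. Continuous
predictors are standardized before fitting; ±1 effect-coded columns are
left untouched (short = −1, combined extensive = +1). Term tests are
drop-in-dispersion F-type tests, F = [(D_red − D_full)/q] / (τ̂/2) on
(q, n − p − 1) degrees of freedom. The scale τ = (√12 ∫f²)⁻¹ is
estimated by a Gaussian-kernel density estimate of ∫f² on the residuals
with Silverman's bandwidth — a consistent estimator chosen because the
reference R package's exact windowing convention is not documented in
the sources used here; coefficient standard errors use the asymptotic
covariance τ²(XᵀX)⁻¹.

## The two-step task and the hybrid model

The simulator implements the canonical two-stage structure: stage-1
choice a₁ leads to its common second-stage state with probability 0.7
(rare: 0.3), stage-2 choice a₂ is rewarded with probabilities that
follow independent reflecting Gaussian random walks (step SD 0.025,
bounds [0.25, 0.75] — the conventional drift when only "gradually
changing" probabilities are specified).

The hybrid model has five parameters: learning rate α ∈ (0,1), stage-1
model-based weight w_MB ≥ 0, stage-1 model-free weight w_MF1 ≥ 0,
stage-2 weight w_MF2 ≥ 0, and perseverance π. Values start at 0.5 (the
midpoint of the 0/1 reward scale). Per trial:

- Q_MB(a) = Σ_s P(s|a) max_{a'} Q₂(s, a'), with P fixed at (0.7, 0.3);
- stage-1 policy: softmax over w_MB·Q_MB + w_MF1·Q_MF1 + π·[a = a_prev];
- stage-2 policy: softmax over w_MF2·Q₂(s₂, ·);
- updates: δ₁ = Q₂(s₂,a₂) − Q_MF1(a₁), δ₂ = r − Q₂(s₂,a₂);
  Q_MF1(a₁) += α(δ₁ + δ₂) (the eligibility-λ = 1 backup, net target r,
  chosen because the model carries a single learning rate),
  Q₂(s₂,a₂) += α δ₂.

Missed trials are skipped in the likelihood. Estimation is MAP:
bounded L-BFGS-B from 10 random starts with weakly informative priors —
Beta(2,2) on α, Normal(0, 5²) on the (bounded-nonnegative) weights,
Normal(0, 2²) on π. With flat priors the MAP tracks the MLE (tested).
The likelihood core is JIT-compiled, which makes the simulate-and-refit
recovery study (30 parameter draws × 1000 trials) run in seconds.
Engagement screens exclude sessions with > 10% missed trials, mean
response times beyond ±2 SD of the cohort mean, or > 90% same-key
presses. A stay/switch logistic analysis (reward × transition
interaction as the model-based signature) is provided as an independent
cross-check on the fitted weights.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; identical seeds give
byte-identical event logs and trial lists. The test suite uses
desk-scale problem sizes chosen to keep each statistical check
well-powered: coefficient recovery at 200 participants, LOOCV selection
over 20 replicate datasets of 18 participants, mixture selection at
45–200 indices per group, the end-to-end habit pattern at 245
participants, and the recovery grid at 30 × 1000 trials. The
acceptance script's common-transition percentage uses a 10,000-trial
session.

## Known limitations

- The conditional dispersion ratio is calibrated for flagging large
  overdispersion, not for testing mild departures (see above).
- BIC mixture selection at these sample sizes requires well-separated
  subgroups; with habitual/goal-directed sensitivities closer than
  roughly {0.1, 0.9} the two-cluster structure of the index is often
  not detected — a property of the index-plus-BIC procedure, not of the
  optimizer.
- MAP with multi-start replaces hierarchical MCMC for the hybrid model;
  per-participant estimates are unshrunken, so extreme weights at low
  trial counts are noisier than a hierarchical fit would give.
- The LOOCV granularity is leave-one-observation-out by default; with
  three observations per participant this keeps two-thirds of a
  participant's information in every training fold, which favours
  conditional prediction accuracy rather than generalization to new
  participants (the leave-one-participant option covers the latter).
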