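# Methods

## Angular conventions

All angles are degrees on [0, 360), counterclockwise.  Signed differences
are wrapped to (−180, 180]; the tie at ±180° maps to +180° so the
difference is single-valued.  Every module shares this convention through
`priorlearn.angles`.

Analyses operate on *signed errors relative to the block's target* rather
than on circular statistics.  At the concentrations used (κ ≥ 5) responses
are tightly localized around the target, so the linear treatment is
adequate; its one visible cost is quantified under *Limits of the normal
approximation* below.

## Task design

A session has `n_blocks` = 40 blocks of 20 trials.  Difficulty
(easy κ = 30 / hard κ = 5) and response order (pro-first / anti-first) are
counterbalanced: each of the four cells receives exactly `n_blocks`/4
blocks.  Targets are drawn without replacement from 20 evenly spaced ring
locations, each serving exactly `n_blocks`/20 blocks.  The response
modality flips after `switch_trial` = 10.  Calibration runs 4 blocks of 10
pro- then 10 anti-saccade trials to 10 evenly spaced locations; each
10-trial half visits every location once in shuffled order (the shuffle is
a design choice; only the location set and the 10+10 structure are fixed by
the task).  Cell and location assignments are shuffled deterministically
from the design seed.

## Generative agents

An agent's internal estimate on trial t, as signed error e_t, is

    e_t = β₀ + Σᵢ wᵍᵢ g_{t−i} + Σⱼ wʰⱼ h_{t−j},   i ∈ 1..3, j ∈ 0..3,

where g are its own previously *reported* guesses (motor noise included —
the agent remembers what it did, not what it intended) and h are hint
errors.  The reported guess adds zero-mean Gaussian motor noise with the
modality's SD.  Defaults mirror the strategy the analysis is built to
detect: wᵍ = (0.3, 0.2, 0.1), wʰ = (0.4, 0, 0, 0), motor SDs 6.3° (pro) and
9.5° (anti) — the calibration-task error SDs of the two modalities.

**Early-trial handling.**  Lags that reach before the block's first trial
are dropped and the remaining weights rescaled to the full weight total, so
trial 1 follows the current hint plus motor noise.  The task only
constrains behavior from trial 4 onward (the fitting window), so this
anchoring rule is a modeling choice; any rule that starts the recurrence
from the hint gives the same fitted window.

**Reset on switch.**  A `reset_on_switch` agent treats the first post-switch
trial like a block start: its usable history begins at trial 11, so trial
11 re-anchors on the hint and lags at trials 12–13 cannot reach across the
switch.  This embodies modality-specific prior learning; with
`reset_on_switch=False` the recurrence runs through the switch unchanged
(full transfer).

**Confidence.**  Ratings are round(offset − scale·σ_internal) clipped to
1..6, with σ_internal = σ_dist/√k for k hints integrated since the last
anchor.  Defaults (offset 6.5, scale 0.2) keep ratings inside the scale for
both difficulties while leaving headroom for the post-switch drop; the
mapping is monotone non-increasing in uncertainty, which is all the
analyses rely on.

## Preprocessing

The estimate is the saccade endpoint for pro responses and its antipode for
anti responses; the analysis variable is the signed error of the estimate
against the target.  Trials with missing angles are flagged
`timeout_or_tracking`.  Trials whose absolute error exceeds 100° —
*strictly*, reading "bigger than 100°" literally — are flagged
`wrong_response_type`: a response executed in the wrong modality lands near
180° after reflection, and 100° separates the two modes of the error
distribution.  The rule is applied after the anti reflection, which is
where wrong-modality trials become separable.  Failed rows are flagged,
never deleted, so exclusion tallies always partition the table.

## Learning metrics and the lower bound

Learning curves are subject-level means per trial index and condition,
then across-subject mean and SEM (SD of subject means / √N).  The
half-block contrast compares per-subject means of trials 1–5 vs 6–10 with a
paired two-sided t-test; zero-variance differences with non-zero mean raise
an error rather than reporting an infinite t.

γ_Motor is each subject's mean absolute calibration error per modality.
The ideal observer's bound combines the motor floor with the sampling error
of the cumulative hint mean:

    γ(t) = √(γ²_Motor + γ²_Hint(t)),   γ_Hint(t) = √(2/π) · σ_dist/√t,

with σ_dist = √(1/κ) converted to degrees.  Because the mean absolute
value of a zero-mean normal is σ√(2/π), quadrature on the
mean-absolute-error scale and on the SD scale give the identical curve —
the two possible readings of the combination rule coincide under
normality.  γ(t) decreases strictly while γ_Hint > 0 and tends to γ_Motor.

### Limits of the normal approximation

σ_dist = √(1/κ) is the high-concentration approximation, not the exact
dispersion of a wrapped von Mises sample (10.46° vs 10.55° at κ = 30;
25.6° vs 27.3° at κ = 5).  Consequently the bound is exact for Gaussian
hint noise of variance 1/κ, and slightly optimistic for true von Mises
hints: the gap is < 0.06° at κ = 30 but ≈ 0.4–1.1° at κ = 5.  These
offsets are far below the between-subject noise at the experiment's scale
(N = 20), but they are resolvable in large Monte Carlo runs; the acceptance
checks therefore verify exact attainment under the bound's own noise
assumptions and approximation-level attainment (< 0.1°) under von Mises
hints at κ = 30.

## Regression model comparison

Predictors are built per block from valid trials only: lagged hints/guesses
skip over failed trials and never cross block boundaries; `cumavg_hint`
includes the current hint, `cumavg_guess` averages strictly previous
guesses.  All eleven models are ordinary least squares per subject,
evaluated on an identical row set (trials 4–10 for the full set, so every
lag-3 predictor exists; 2–10 for the single-predictor robustness set).
Zero-variance predictors are dropped with a warning.

BIC uses the Gaussian-likelihood form n·ln(RSS/n) + k·ln(n) with k counting
the coefficients (intercept included) plus the error variance; the variance
term is irrelevant to BIC differences but stated for reproducibility.
Bayesian weights are exp(−Δᵢ/2)/Σⱼexp(−Δⱼ/2) with Δᵢ = BICᵢ − min BIC; they
sum to one per subject and are invariant to shifting all BICs.  The group
result is the mean weight across subjects; per-subject winners are
available from the per-subject weight matrix.

Stepwise selection predicts each block's trial-10 guess error from that
block's guess errors 1–9 and hint errors 1–10, with blocks as rows: greedy
forward selection minimizing mean 10-fold cross-validated RMSE, folds
assigned by a seeded permutation, stopping when no candidate improves the
criterion.  The intercept-only (null) model's RMSE is always reported.

Time-resolved weights refit a small model (by default guess_{t−1} and
hint_t) at each trial index across a subject's blocks; predictors undefined
at an index (the lagged guess on trial 1) are omitted there.  Group
significance is a two-sided one-sample t-test of the subject weights
against zero.  The pro-vs-anti weight contrast fits the full lag model
separately per modality on windows whose whole lag history stays inside one
modality half (trials 4–10 and 14–20) and compares the previous-guess and
current-hint weights with paired t-tests.

## Transfer analysis

Cross-modality contrasts subtract each subject's γ_Motor of the modality in
use from the per-subject per-trial-index mean — at the level of means, not
single trials, for stability; corrected values may be negative.  Contrasts
of trial 11 against trials 10 and 1 use paired two-sided t-tests per
condition cell and pooled (within-subject average over cells); the
within-modality variant pools over block order and needs no correction,
since both trials share the same motor floor.  No multiple-comparison
correction is applied — the output carries an explicit flag.

The three-way repeated-measures ANOVA (difficulty × trial × order, all
within subject) uses the standard balanced within-subject F decomposition
(statsmodels `AnovaRM`), requiring a complete design and naming the
offending cell otherwise.  Sphericity is not an issue for the two-level
factors used here.  An all-constant input returns F = 0 / p = 1 rather
than a 0/0 artifact.

## What the synthetic data do and do not show

The generator reproduces the statistical structure the analyses assume:
counterbalanced designs, von Mises hints, lag-weighted agents, Gaussian
motor noise, resettable history, uncertainty-coupled confidence.  Passing
tests therefore demonstrate that the pipeline *recovers known ground truth
under its own assumptions* — learning curves track the bound for optimal
agents, model comparison identifies generative strategies (≥ 90% of
cohorts at 20 subjects × 40 blocks), lag weights are recovered to ±0.05,
and resetting agents reproduce the full response-switch phenomenology
(trial-11 error back at naive levels, previous-guess weight ≈ 0 at trial 11
only, hint weight peaking at trials 1 and 11).

They do not show robustness to features real data may have: non-Gaussian
or fat-tailed motor noise, drifting attention or lapses, latency-dependent
errors, response biases toward salient locations, or miscalibrated
confidence.  Gaze-stream artifacts (fixation detection, tracking loss) are
abstracted into a binary failure flag.

## Problem sizes and runtime choices

Simulation-based checks run at the study's scale — 20 subjects × 40 blocks
— with 2000 blocks for Monte Carlo optimality curves, 50 cohorts for model
recovery, and 1000 (tests) / 500 (script) replicates for type-I-error
calibration of the ANOVA; these sizes give binomial/MC standard errors
comfortably inside the asserted tolerances while keeping a full run in the
low minutes.
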