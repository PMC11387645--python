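# Methods

This package implements, end to end on synthetic cohorts, the computational
analysis of two-step-task behavior combined with single-trial EEG: hybrid
model-free/model-based reinforcement learning with per-subject maximum-
likelihood fitting and BIC model selection, trial-wise reward-prediction-
error (RPE) extraction, robust mass-univariate first-level regression of
feedback-locked EEG with FDR-corrected group maps, and second-level robust
regression of windowed RPE effects (FRN, P3) onto impulsivity (BIS-11),
compulsivity (OCI-R) and the model-based weight *w*.

## Task model

Three states (stage 1: s_A; stage 2: s_B, s_C), two actions per state.  A
stage-1 choice leads to its preferred stage-2 state with probability
p_common = 0.8 (a *common* transition) and to the other state otherwise
(*rare*).  Stage-2 outcomes are integer points drifting across trials.

The task description conflates two readings of the outcome process; both
are implemented (`TaskConfig.walk_mode`):

- **magnitude** (default): each of the four stage-2 options carries an
  integer point value in [-4, +5]; every trial, each value independently
  moves ±1 point with probability 0.2, reflecting at the bounds.  The
  realized outcome is the chosen option's current value.
- **probability**: each option carries a reward probability drifting as a
  reflective Gaussian walk in [0.25, 0.75] (step SD 0.025); outcomes are
  binary 1/0 points.

The two readings are not interchangeable for the classic stay-probability
analysis.  Under the magnitude walk, graded outcomes dichotomized to
rewarded/unrewarded create an exploration-selection confound: pure
model-free agents show a sizable spurious reward-by-transition interaction
(it persists with the eligibility trace at 0 or 1 and with a frozen walk,
so it is not a learning artifact).  Under the probability walk the
canonical dissociation is clean: model-free agents show a reward effect
with an interaction near zero, model-based agents the reverse, as the
behavioral-signature checks verify.  That validation therefore runs under
the probability walk; everything else uses the magnitude default.

Sessions are 500 trials; a four-block structure is recorded as metadata
only.  Synthetic response times are log-normal (medians 500/450 ms, sigma
0.25) with a +30 ms additive shift of the stage-2 RT on rare transitions,
giving the RT-delta analysis a known target.  Misses and fast responses are
absent by default and can be injected (`miss_rate`, `fast_rate`) to
exercise the downstream filters.

## Learning model

Model-free values follow SARSA(lambda) with both updates applied at the
second stage (r1 = 0):

    delta1 = Q(s2, a2) - Q(s1, a1)
    delta2 = r - Q(s2, a2)
    Q(s1, a1) += alpha * delta1 + alpha * lambda * delta2
    Q(s2, a2) += alpha * delta2

Model-based stage-1 values plan over the *true* transition matrix
(Q_MB = P(s_B|a) max Q(s_B, .) + P(s_C|a) max Q(s_C, .)); the hybrid agent
mixes Q_net = w Q_MB + (1 - w) Q_MF.  Choices are softmax with inverse
temperature beta plus choice stickiness pi (repeat the previous stage-1
stimulus) and response stickiness rho (repeat the previous key); stage 2
uses plain softmax.  Q values start at 0 and are never reset; the
eligibility trace is zeroed at each trial start.  Missed trials contribute
no likelihood, carry Q forward, and reset the stickiness indicators.

Rewards are scaled by 1/reward_max (points / 5) before entering the model,
so they lie in [-0.8, 1]; the scale is absorbed by beta and leaves the
fitted w invariant (tested to ±0.05).  Under the probability walk the scale
is 1.

delta2, the signed stage-2 RPE computed with pre-update values, is the
trial-wise regressor used by all EEG analyses.

## Fitting and model comparison

Nine variants: {MF (w=0), MB (w=1), hybrid (w free)} x {no stickiness,
+choice, +choice+response}.  lambda is dropped from the MB variants, where
it does not enter the likelihood.  Estimation is pure maximum likelihood —
multi-start (default 20) L-BFGS-B in transformed space (logit for alpha,
lambda, w; log for beta with a cap at 20; identity for pi, rho), objective
tolerance 1e-6.  No priors are used; the estimation protocol is this
package's own design.  BIC = k ln(n_obs) - 2 LL with n_obs counting both
choices of every complete trial; variants are ranked by summed BIC across
subjects, ties toward fewer parameters.

The likelihood trial loop is numba-compiled; an independent pure-Python
step-by-step trace oracle in the test suite verifies it to 1e-12.
Parameter recovery at 100 subjects x 500 trials yields corr(true w,
fitted w) above 0.8, and model recovery at 30 subjects selects the
generative hybrid+choice variant by summed BIC (both recomputed by the
validation suite).

With fixed stimulus positions (the default) the rep and resp indicators
coincide, so pi and rho are jointly unidentified — only their sum matters —
and the +choice+response variant can never beat +choice by BIC.  A
position-shuffling flag separates them.

## Behavioral statistics

*Screening.*  Per subject, logistic regression stay ~ reward_prev +
reward_prev:transition_prev; a subject is kept when either coefficient is
positive with one-sided p < .05 (threshold configurable; the criterion
"positively associated" needs a concrete
operationalization; this one is the package's own).  Perfect separation falls back to a ridge-penalized fit with
Hessian SEs, flagged in the diagnostics.

*Stay GLMM.*  Rows from trial 2 onward: stay ∈ {0, 1}, previous-trial
transition (common +1 / rare -1) and reward (points > 0 → +1, else -1;
zero-point "nothing" outcomes count as non-reward), BIS-11 and OCI-R sum
scores z-scored across the included sample.  The model
stay ~ transition\*reward\*BIS\*OCI + (transition\*reward | subject) is
solved by lme4's glmer (binomial, bobyqa) through Rscript; nAGQ = 0 by
default for speed on the full random-slope structure.  Non-convergence
triggers a flagged random-intercept refit; without R a subject-clustered
plain logistic fallback is used and flagged.  Fixed effects are reported
exponentiated.  Gender, when present, enters the behavioral model only
(coded ±0.5).

*RT delta.*  Median stage-2 RT on rare minus common trials per subject
(stage-1 available behind a flag), regressed on BIS\*OCI by robust
regression at the cohort level.

## Synthetic EEG

Epochs are -200..1000 ms at 500 Hz (channels FCz, Cz, Pz, F3, F4; a
minimal stand-in for a full montage — topography is out of scope).
Background noise is Gaussian, low-passed at 30 Hz, SD 10 uV.  Two
Gaussian-windowed component templates are planted: FRN at FCz (peak 294 ms,
FWHM 60 ms, negative base -3.5 uV, 1.44 uV more negative on common trials)
and P3 at Cz (peak 370 ms, FWHM 120 ms, base +7 uV, +2.6 uV on rare
trials).

Per-trial RPE modulation: the FRN amplitude rises with a 50/50 mixture of
the z-scored signed RPE and a valence step (so the deflection is smaller —
less negative — after positive RPEs, a valence-dominated response); the P3
rises with a 50/50 mixture of signed RPE and |RPE| (surprise).  A pure
|RPE| drive would leave the linear first-level RPE regressor with no
expected slope under a symmetric RPE distribution; the signed component
mirrors the positive linear RPE effect the analysis is designed to detect
and keeps the second-level links identifiable.

Each subject's modulation coefficient per component and transition type is

    a = base(component, transition) + links · (w_z, bis_z, oci_z) + noise,

with traits from a correlated bivariate normal (BIS 65 ± 10, OCI 12 ± 9,
r = 0.3) and w = logistic(-0.5 · oci_z + N(0, 0.8)) — higher compulsivity,
less model-based control.  Agent parameters: alpha ~ U(0.3, 0.8), lambda ~
U(0.3, 0.9), beta ~ logN(ln 5, 0.3), pi ~ N(0.25, 0.1), rho = 0.

*Calibration.*  Planted peak coefficients reach the recovered window-mean b
values through cell-specific transfer factors (subset z-scaling of the RPE
regressor plus the valence/|RPE| projections).  These were measured once on
a 250-subject calibration cohort and frozen (`TRANSFER`,
`PIPELINE_NOISE_SD` in `cohort.py`); the defaults are set so the
*recovered* quantities land on the magnitudes the analysis targets:
window intercepts ≈ (2.09, 1.16) uV for the FRN and (1.01, 0.06) uV for the
P3 (common, rare), trait links ≈ +0.31 uV/z for w on the FRN and -0.45 uV/z
for OCI on the rare-trial P3, and a between-subject residual SD of ≈ 2.0-
2.6 uV.  `expected_window_slope` exposes the planted-to-recovered mapping
for recovery tests.  The constants are valid for the default drive
mixtures, templates and task settings only.

What the generator does **not** emulate: 1/f spectra, ocular/cardiac
artifacts, volume conduction, channel covariance, learned (rather than
instructed) transition knowledge, block effects.  Passing tests show the
statistical pipeline recovers what was planted under these idealized
conditions; they do not certify preprocessing choices against real
recordings.

## First-level EEG analysis

Pipeline order (logged): fast-response filter (either stage RT < 100 ms) →
adaptive artifact rejection → baseline correction (-200..0 ms) → single-
trial regression.

*Artifact rejection.*  Each trial is summarized by its RMS amplitude over
channels and time; the deviation score is that summary's z value under a
robust (median/MAD) across-trial distribution, so artifact trials cannot
mask themselves.  Starting at 4 SD, the threshold steps down by 0.1 until
at least one trial is rejected and up by 0.1 until at most 5% are; the
final threshold is reported.  The exact deviation statistic of the original
toolbox is unspecified; this operationalization satisfies the stated
constraints.

*Regression.*  EEG ~ transition + RPE + transition x RPE at every
(channel, time) point, with transition coded common = +1 / rare = -1 (fixed
so that the rare > common amplitude pattern appears as a negative
transition b)
and RPE z-scored within subject (within the entering trial subset).
Within-transition analyses drop the transition columns.  The estimator is
Huber M-estimation (tuning constant 1.345, 95% Gaussian efficiency), IRLS
vectorized across all outcome points, max 50 iterations, tolerance 1e-8.
The residual scale is the uncentered MAD of the initial OLS residuals (the
statsmodels convention), held fixed while the coefficients iterate
(one-step-scale M-estimation); c = inf reduces exactly to OLS (tested), and
single points agree with statsmodels RLM(update_scale=False).

*Group maps.*  Per (channel, time): two-tailed one-sample t against zero
over subjects; Benjamini-Hochberg FDR at q = 0.05 with the family spanning
all time points at FCz and Cz (the two component channels; a whole-scalp family
is available).  Zero-variance points get p = 0 (mean ≠ 0) or 1, flagged.

*Windows.*  On the grand average across subjects: FRN = most negative
sample at FCz in 250-350 ms, P3 = most positive at Cz in 330-430 ms, ties
to the earlier latency, boundary peaks warned.  Effects are summarized as
the mean RPE b over ±25 ms around each peak.

## Second-level analysis

Per component and transition type, windowed RPE b values are regressed on
z-scored BIS, OCI and w with all interactions (8 terms; products of
z-scored mains, not re-standardized) by Huber robust regression
(statsmodels RLM; SEs from the standard M-estimation covariance).  No
multiple-testing correction across the table (a flag exists, default off).
Interactions are followed up by single-predictor fits in median-split
groups (ties assigned to the low group, deterministically) and coefficient
pairs compared by z = (b1 - b2) / sqrt(se1² + se2²).

## Validation design and problem sizes

The validation suite runs the pipeline at sizes chosen to keep the full
suite in single-digit minutes on one core while preserving the study
conditions that matter: equation oracles to 1e-12; behavioral signatures at
30 subjects x 500 trials (probability walk); parameter recovery at 100
subjects x 500 trials x 20 restarts; model recovery at 30 subjects x 9
variants; null FDR calibration over 200 replicates of 8-subject gain-free
cohorts (every significant point a false positive; the mean significant
fraction must not exceed q plus two Monte-Carlo SEs — under a global null
the BH-expected fraction is far below q); planted-effect sign/window checks
at 40 subjects; Huber-vs-OLS robustness with 5% gross outliers; and six
replicate 200-subject end-to-end studies checking sign recovery (≥ 90%) and
2-SE agreement of the planted w→FRN and OCI→P3 links.  The end-to-end runs
analyze the two component channels and use the generator's true w and
true-parameter RPE series as covariates, isolating the EEG chain from
estimation error in the fitting path, which is validated separately.

## Known limitations

- The magnitude-walk stay-probability confound means behavioral MF/MB
  signatures should be interpreted against the probability-walk baseline.
- Transfer constants are empirical and tied to the default generator
  settings; changing mixtures or templates requires recalibration.
- With fixed stimulus positions pi and rho are jointly unidentified.
- The second-level SEs slightly understate between-replicate variability of
  the P3 links (the |RPE| drive adds subject-level slope jitter).
- Real-data preprocessing (filtering, ICA, re-referencing) is out of scope;
  synthetic epochs are generated clean.
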