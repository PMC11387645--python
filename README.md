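# twostep-eeg

Hybrid model-free/model-based reinforcement learning on the two-step task,
combined with single-trial EEG analysis of feedback processing — as a
tested, reusable Python pipeline exercised end to end on synthetic cohorts.

The scientific question this pipeline serves: how do trial-wise reward
prediction errors (RPEs) modulate feedback-locked EEG components — the
feedback-related negativity (FRN, fronto-central, ~250–350 ms) and the P3
(centro-parietal, ~330–430 ms) — and how is that modulation moderated by
trait impulsivity (BIS-11), compulsivity (OCI-R), and the degree of
model-based control (*w*)?  It is aimed at computational-psychiatry and
decision-neuroscience researchers who want the full chain — task
simulation, RL model fitting, mass-univariate robust EEG regression, trait
moderation — with every stage testable against planted ground truth.

## The model

Agents solve the two-step task (80/20 stage-1→stage-2 transitions, drifting
point outcomes in [−4, +5]) with SARSA(λ) model-free learning,

    δ₁ = Q(s₂,a₂) − Q(s₁,a₁),     δ₂ = r − Q(s₂,a₂),
    Q(s₁,a₁) += αδ₁ + αλδ₂,       Q(s₂,a₂) += αδ₂,

model-based planning over the true transition matrix
Q_MB(a) = P(s_B|a)·max Q(s_B,·) + P(s_C|a)·max Q(s_C,·), hybrid arbitration
Q_net = w·Q_MB + (1−w)·Q_MF, and a stickiness softmax
P(a) ∝ exp(β(Q_net(a) + π·rep(a) + ρ·resp(a))).  Nine variants (3 families
× 3 stickiness levels) are fitted per subject by multi-start MLE and
compared by BIC.  The signed stage-2 RPE series δ₂ drives the EEG
analyses: per-subject robust regression EEG ~ transition + RPE +
transition×RPE at every (channel, time) point, FDR-corrected group t-maps,
and second-level robust regressions of window-mean RPE effects on
z-scored BIS, OCI and w with all interactions.

See `docs/methods.md` for assumptions, parameter defaults, and the
synthetic-data calibration.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # traits, agents, 60 x 500 trials
python analysis/02_fit_models.py          # per-subject MLE + BIC comparison
python analysis/03_behavior_analysis.py   # screening, stay GLMM, RT delta
python analysis/04_eeg_firstlevel.py      # epochs -> robust b maps -> group maps
python analysis/05_second_level.py        # trait moderation of RPE effects
```

Abridged output actually printed by these scripts at their default seeds:

```
simulated 60 subjects x 500 trials
  realized common-transition rate: 80.2%
  BIS-OCI correlation: 0.32
  w range: 0.14-0.89 (corr with OCI z: -0.51)

fitted 60 subjects with hybrid_choice (20 restarts)
  median fitted w: 0.46; corr(true w, fitted w) = 0.72
  BIC winner over 10 subjects: hybrid_choice

screening kept 53/60 subjects
stay GLMM (lme4/glmer; fallback=False):
  reward                   exp(b)= 1.45  p=3.48e-22
  transition               exp(b)= 0.82  p=2.62e-09
  transition:reward        exp(b)= 1.59  p=1.55e-41
RT delta (rare - common): intercept 27.6 ms (n=53)

processed 60 subjects (mean artifacts removed: 1.2)
  FRN: peak 294 ms at FCz, window (269.0, 319.0)
  P3: peak 374 ms at Cz, window (349.0, 399.0)
  transition: 119 FDR-significant (channel, time) points
```

Reading: simulated agents show both a reward main effect (model-free
staying, exp(b) = 1.45) and a reward×transition interaction (model-based
staying, exp(b) = 1.59); the planted rare-transition slowing (+30 ms) is
recovered at 27.6 ms; the FRN/P3 peaks are found at their planted
latencies; and the transition effect (rare > common P3, negative b under
common=+1 coding) survives FDR correction.

## Layout

```
src/twostep_eeg/    task, hybrid, fitting, behavior, cohort,
                    firstlevel, secondlevel, experiments
analysis/           numbered narrative drivers (write under results/)
tests/              pytest suite incl. independent equation-trace oracles
scripts/            acceptance.py
docs/methods.md     model, calibration, numerical choices, limitations
```
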