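# fruitbox

Simulation and reinforcement-learning model fitting for a two-choice
discrimination learning ("fruit box") task, of the kind used to study
feedback-based learning deficits in Parkinson's disease.

On each of 96 trials (8 blocks × 12), one of six discriminative stimuli is
shown and the subject presses LEFT or RIGHT; three stimuli are rewarded for
LEFT, three for RIGHT, and the contingencies never change. The package:

* builds and validates the counterbalanced, block-randomized task schedule;
* simulates Q-learning agents and whole synthetic cohorts (a control-like
  group and a PD-like group, with clinical covariates and region-of-interest
  gray-matter values with a known coupling structure);
* recovers each subject's **learning rate α** and **exploration parameter β**
  from their trial-by-trial choices by grid-search maximum likelihood;
* runs the downstream analyses: block-accuracy curves, permutation-based
  group contrasts, a clinical covariate screen, and marginal + partial
  ROI–behavior correlations.

## Model

One weight `W ∈ [0, 1]` is kept per (stimulus, response) pair. On each
trial the choice follows a softmax over the presented stimulus's two
weights, with inverse-gain (exploration) parameter β:

    P(A) = exp(W_A/β) / (exp(W_A/β) + exp(W_B/β))

Feedback US is 1 for a correct response and 0 otherwise, and only the chosen
pair's weight is updated by the delta rule with learning rate α:

    PE(t) = US(t) − W(t),     W(t+1) = W(t) + α · PE(t)

Fitting replays the observed choices, accumulates the session log-likelihood
`LLE = Σ_t log P(choice_t)`, and maximizes it over a dense (α, β) grid
(step 0.01; β = 0 excluded as degenerate). Fit quality is summarized by a
pseudo-R² against a purely random responder (p = 0.5 on every trial):

    pseudo-R² = 1 − LLE / r,     r = 96 · ln(1/2)

which is 0 at chance and 1 for perfect prediction; the grid's α = 0 point
reproduces the random responder exactly, so fitted values are never
negative.

## Worked example

```python
from fruitbox import (AgentParams, build_schedule, fit_grid, make_contingency,
                      simulate_session, block_accuracy, overall_accuracy)

contingency = make_contingency(seed=7)          # 3 LEFT / 3 RIGHT, outcomes counterbalanced
schedule = build_schedule(contingency, seed=8)  # 8 blocks x 12, each stimulus twice per block
agent = AgentParams(alpha=0.217, beta=0.70)     # control-group generating values
session = simulate_session(agent, contingency, schedule, seed=9)

print("overall accuracy:", round(overall_accuracy(session), 3))
print("block accuracy:", block_accuracy(session).acc.round(2))
print(fit_grid(session, contingency))
```

prints

```
overall accuracy: 0.667
block accuracy: [0.5  0.67 0.75 0.67 0.42 0.75 0.83 0.75]
FitResult(alpha_hat=0.36, beta_hat=0.94, lle=-60.160457, pseudo_r2=0.095904, n_trials=96)
```

The agent learns within the session (block accuracy drifts upward from
chance), and the grid fit recovers parameters in the right region — though
a single 96-trial session identifies (α, β) only loosely at this
explorative β, which is why recovery is always assessed over many simulated
subjects (see `fruitbox.experiments`).

The same pipeline is available from the shell:

```sh
fruitbox simulate --seed 0 --out-dir data/          # trial + cohort tables
fruitbox fit --trials data/trials.csv --out fits.csv
fruitbox report --fits fits.csv --cohort data/cohort.csv --out report/
fruitbox assoc --fits fits.csv --cohort data/cohort.csv --out assoc.csv
```

All interchange files are plain delimited text, so real exported behavioral
data in the same long trial-table format (`subject_id, trial_index, block,
stimulus, response, correct`) can be fitted directly.

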