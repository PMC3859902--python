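# Methods

## Task model

The simulated task is a six-stimulus, two-response instrumental
discrimination: 96 trials in 8 blocks of 12, each stimulus presented exactly
twice per block in an independently randomized order. Three stimuli are
rewarded for LEFT and three for RIGHT; each stimulus also maps bijectively
to a distinct outcome identity. Counterbalancing across subjects is realized
as a seeded uniform draw of both the LEFT/RIGHT assignment and the
stimulus→outcome bijection (`make_contingency`); a Latin-square scheme would
also be defensible, but per-subject uniform randomization is simpler and
makes the marginal role of every stimulus symmetric across seeds, which the
suite verifies. Stimuli are abstract labels (`S1`..`S6`); timing, sounds and
point scoring are presentation detail outside the model.

Feedback is deterministic: the correct response always yields US = 1, the
incorrect one US = 0. Hence `us == correct` on every trial, and the long
trial table omits the redundant column.

## Choice model

Weights are kept per (stimulus, response) pair — 12 values — because the
task requires choosing LEFT vs RIGHT *per stimulus*. Choices follow a
two-option softmax with inverse gain β over the presented stimulus's two
weights; only the chosen pair is updated, by the delta rule with learning
rate α. Weights initialized in [0, 1] stay there (the update is a convex
combination), so the weight margin is bounded by 1 and the single-trial
log-loss by 1/β.

`w_init = 0.5` for all pairs, shared by generator and fitter. The midpoint
of the US range makes negative feedback informative from trial 1, and —
critically — makes the α = 0 grid point reproduce the p = 0.5 random
responder exactly, which guarantees a non-negative pseudo-R².

## Fitting

Maximum likelihood by exhaustive search on a grid with step 0.01: α from 0
to 1 (101 values), β from 0.01 to 1 (100 values). β = 0 is excluded: it
degenerates the softmax into a step function with zero-probability events
and LLE = −∞. Exact likelihood ties (which occur along the whole β axis at
α = 0) are broken toward the smallest β, then the smallest α, so fits are
deterministic.

The grid evaluation exploits that the weight trajectory depends on α but not
β: the session is replayed once per α (vectorized across the α axis),
recording the chosen-minus-unchosen margin per trial, and the β axis is then
applied by broadcasting. Likelihoods are accumulated in log space via
`logaddexp`; choice probabilities are computed as per-side sigmoids of the
scaled margin, never as `1 − p`, which would cancel catastrophically at
saturated margins. The sequential scalar replay (`session_loglik`) and the
vectorized grid agree to ~1e−12, and both agree with an independent
brute-force replay oracle in the test suite.

The pseudo-R² is implemented in McFadden form, `1 − LLE/r` with
`r = n·ln(1/2)`. The alternative sign convention `(LLE − r)/r` is negative
for better-than-chance fits; the McFadden form has the conventional
orientation (0 = chance, 1 = perfect) and is the one the reported statistics
of such analyses carry.

## Synthetic cohorts

The generator emulates a two-group patient study: 11 control-like and 17
PD-like subjects. Per-group (α, β) are drawn from normal distributions
truncated to the grid's support — defaults α ~ N(0.217, 0.036²) (control)
and N(0.163, 0.041²) (PD), β ~ N(0.70, 0.26²) and N(0.85, 0.30²) — the
group means/SDs a comparable patient study reports. Normality is the
generator's assumption; only means and SDs are constrained by the source
values.

Clinical covariates (disease duration, Hoehn & Yahr stage, UPDRS-III,
dopamine dose equivalent, BDI) are independent truncated normals clipped to
plausible ranges, drawn for every subject and by construction uncoupled
from α; they exist to exercise the null covariate screen (the screen is run
on the PD subset, mirroring the clinical analysis it emulates).

ROI gray-matter values use a single-latent-driver structure: standardized
vmPFC = roi_effect·z(α) + noise (default roi_effect = 1, giving a
population vmPFC–α correlation of roi_effect/√(roi_effect²+1) ≈ 0.71, ample
power at n = 17); rIFG and NAcc load on standardized vmPFC with weight
roi_cross_corr (default 0.5) and have **no direct α coupling**, so their
marginal association with α flows entirely through vmPFC and vanishes once
vmPFC is partialled out. Values are affinely rescaled to density-like units
(0.45 ± 0.05 per latent SD); correlations are scale-invariant. This is a
deliberate abstraction of a voxelwise morphometry analysis down to ROI
summaries: the partial-correlation logic is the implementable content, the
voxelwise preprocessing is not modeled, and nothing about the synthetic ROI
values is a claim about real anatomy.

What passing tests on these cohorts show is that the *pipeline* recovers a
planted structure of this shape; real gray-matter data have spatial
covariance, site effects and non-normal tails the generator does not
emulate.

## Statistics

Group contrasts default to a seeded two-sided permutation test on the mean
difference (10,000 label shuffles, add-one p estimator, which cannot return
0); Welch's t and Mann–Whitney U are provided for parity with standard
toolboxes. Repeated-measures ANOVA machinery (sphericity corrections,
post-hocs) is intentionally not reimplemented; block-wise contrasts with
permutation tests cover the same scientific question in this package's
scope. Partial correlation uses the residual method (OLS with intercept on
the control regions, correlate residuals), with permutation inference on
the measure residuals; near-collinear controls (design condition number
above 1e8) or a target fully explained by the controls are flagged rather
than reported as numbers.

## Parameter identifiability and recovery — known limitations

With 96 trials and an explorative β (≳ 0.6), (α, β) are only weakly
identified: the weight margin never exceeds 1, so β ≥ 0.7 caps the
per-trial choice probability near 0.8, the data look close to Bernoulli,
and the average log-likelihood surface is nearly flat in β above ~0.6. The
`fruitbox.experiments.recovery_experiment` measurements (which the
validation suite and the reproduction script run) show the consequences at
the default generating values:

* recovered α is heavy-tailed: its median tracks the truth (≈ 0.22 at true
  0.217) but boundary fits near α̂ = 1 pull the *mean* up to ≈ 0.30 for the
  control-like group; the PD-like mean (≈ 0.17 at true 0.163) is close;
* recovered β is biased toward the grid interior (mean ≈ 0.56–0.62 for both
  true 0.70 and 0.85): upward errors are clipped at the grid bound β = 1
  while downward errors are not, and the flat surface lets single-session
  fits land anywhere in a broad β range;
* per-subject recovery noise (SD(α̂) ≈ 0.25–0.31) is several times the true
  between-group gap (0.054), so at n = 11 vs 17 the recovered-α group
  contrast has the correct direction in only ~70–76% of simulated cohorts
  and rarely reaches significance.

These are properties of the estimator at these study conditions, not bugs:
the likelihood implementation is verified against an independent
enumeration oracle, and the expected-surface argmax sits near the truth for
α while being flat in β. Real subjects are not Q-learning agents; fitted
parameters on real data can be far less variable than model-generated
recovery at the same values, which is why the recovery experiments are
reported as measured rather than assumed. In exploitative regimes
(small β) the likelihood instead develops genuine plateaus — e.g. data
generated at (α = 0.5, β = 0.05) are near-deterministic and fit equally
well by a ridge of (α, β) pairs, with α̂ concentrating around 0.75 — so
point recovery of α should only be expected in intermediate regimes;
rank-order recovery (Spearman ≈ 0.4 across subjects spanning α ∈
[0.05, 0.45]) is the realistic claim.

## Problem sizes

Default experiment sizes — 200 sessions per recovery arm, 200 replicate
cohorts for the contrast and ROI experiments (grid step 0.02 for the
cohort-fitting experiment), 500 sessions for the random-responder control —
were chosen so each experiment's Monte-Carlo error on the quantities it
reports is a few percent; all run in minutes on one CPU.
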