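# Methods

## The scientific problem

In classic reinforcement learning every value-coding unit estimates the
mean of the reward distribution; in distributional RL, units apply
different weights to positive and negative reward prediction errors
(RPEs, δ = r − V) and therefore converge to different **expectiles** of
that distribution. The τ-expectile of X is the unique e with
τ·E[(X−e)₊] = (1−τ)·E[(e−X)₊]; τ = 0.5 gives the mean. A unit with
learning rates α⁺ (δ>0) and α⁻ (δ≤0) converges to the expectile with
τ = α⁺/(α⁺+α⁻), so "optimism" is a single latent position in (0,1) that
should show up consistently in three measurable signatures: where the
unit's choice response reverses sign (reversal point), how steeply its
feedback response scales positive vs negative RPEs (scaling asymmetry),
and how fast it updates after positive vs negative surprises (learning
asymmetry). This package estimates all three and tests their mutual
consistency.

## Task models

**Static probabilistic-cue task.** Five value levels map to reward
probabilities {0.1, 0.3, 0.5, 0.7, 0.9}. Each trial offers one of the four
adjacent-level pairs (uniformly); the higher option is chosen with
probability `accuracy` (default 0.98, near-ceiling performance); reward is
Bernoulli in the chosen probability; each level is denoted by one of two
stimulus sets. Because the lowest level is almost never chosen, analyses
use the four *chosen* values on a 1–4 axis (`chosen_value_level =
chosen_level − 1`; the rare level-0 trials are masked). The feedback-epoch
RPE is δ = r − p with p the cued probability — the cue fully specifies the
gamble, so no learned value is involved in this task.

**Dynamic reversal-learning task.** Four cues each carry one of three
reinforcement levels, coded {0, 0.5, 1} (the magnitudes are a declared
convention — equally spaced on the unit interval so δ ∈ [−1, 1]; the
original task reports only "low/medium/high"). A cue's level is constant
for 5–9 *encounters of that cue* and is then redrawn uniformly over the
three levels (it may repeat). Cue choice is uniform by default (a softmax
over running values is available); all neural analyses condition on the
realized choice/reward sequence, so the behavioural policy is deliberately
minimal.

## Neuron model

A unit's window-averaged rate is an affine read-out of an asymmetrically
scaled RPE:

    rate = baseline + coding_sign · gain · asym(δ; S) + ε,  ε ~ N(0, noise_sd²)

with asym(δ; S) = 2Sδ for δ > 0 and 2(1−S)δ for δ ≤ 0. The factor 2 makes
S = 0.5 the identity, so a symmetric unit is exactly linear and `gain` is
"rate change per unit RPE of a symmetric unit". The same convention is
used in both tasks, so gain and noise_sd are comparable across them; it
differs from the fitted single-S read-out (x = δS / δ(1−S)) only by a
factor 2 that the fitted slope absorbs, and no estimator is sensitive to
it. In the static task the choice-epoch deviation is v − V_τ with V_τ the
τ-expectile (from the oracle) of the session's chosen-value distribution —
an optimistic unit's prediction sits high, so its response is negative for
all but the highest values. In the dynamic task the per-cue value evolves
as V ← V + α⁺δ (δ > 0) / V ← V + α⁻δ (δ ≤ 0) from v_init = 0.5
(mid-range). Zero-δ updates are routed to the α⁻/(1−S) branch throughout.

Noise is Gaussian on the window-averaged rate because every estimator
consumes window-averaged rates; the 200–600 ms analysis window is a
property of the rate-extraction layer (and of real-data readers), not of
the estimators. What the generator does *not* emulate: spike-train
autocorrelation, slow drifts, behavioural covariates (motivation, eye
movements), across-session nonstationarity. Passing tests therefore show
the estimators are correct and well-calibrated under idealized rate noise,
not that real recordings will reach the same effect sizes.

**Populations.** Per-unit τ ~ Uniform(0.2, 0.8): wide enough to span
strong optimists and pessimists while avoiding the degenerate extremes
where one RPE branch has near-zero scaling and β-ratio estimates become
unstable. With `coupled=True` (the distributional-RL arrangement),
S = τ and α⁺/(α⁺+α⁻) = τ with α⁺+α⁻ ~ Uniform(0.2, 0.8); uncoupled
populations draw S independently (a negative control). `topography_slope`
∈ [−1, 1] is the target correlation between τ and the anterior–posterior
coordinate, realized by mixing the standardized τ with independent
Gaussian noise. Half the units code negatively (sign −1) by default, and a
configurable distractor fraction is split between task-insensitive units
and same-sign (non-RPE) value coders to exercise the screens.

## Estimators and conventions

**Screens.** Static: value-selective at choice (p < 0.05), value-selective
at feedback with the *opposite* sign, with the rewarded- and
unrewarded-trial feedback regressions run separately and required to agree
in sign. (Pooling the feedback trials would be wrong: for a symmetric RPE
unit the pooled expected slope is exactly zero, since the rewarded and
unrewarded branches cancel.) Dynamic: rate ~ RPE regression, with the RPE
proxy from a canonical symmetric Rescorla–Wagner (α = 0.5, v_init = 0.5)
run on the realized sequence — screening needs only a monotone proxy for
δ. The stricter current-vs-previous-reward criterion
(FR = β₀ + β₁Rew(t) + β₂Rew(t−1), both significant, opposite signs) is
also provided. Negative coders are reflected about their mean rate
(an exact involution, idempotent via an alignment flag) so the population
shares a positive convention. Cells with fewer than 10 trials in any
regression condition are excluded with a logged reason, never passed
silently.

**Reversal point.** Rates z-scored across the analysed trials; per-level
means scanned in increasing order; the first adjacent pair changing sign
from negative to non-negative defines the crossing, linearly interpolated
to zero. Non-monotone profiles are flagged `multiple_crossings` (the first
crossing is reported, deterministically); profiles with no crossing are
flagged and *excluded* from correlation analyses rather than clamped to
the scale ends, which would manufacture spurious extreme optimism. Note
that after z-scoring the trial-weighted level means sum to zero, so the
only realizable no-crossing profile is a monotone-decreasing one.

**Asymmetric scaling.** β⁺ and β⁻ are the negated slopes of the feedback
rate on cued probability among rewarded and unrewarded trials
(for a sign-aligned RPE unit both raw slopes are negative because δ = 1−p
and δ = −p both decrease in p). If either β is negative beyond a tolerance
of 10⁻⁶ × the rate scale, or β⁺+β⁻ ≤ 0, the ratio is undefined and the
unit flagged `unstable_ratio`. The composite "neuron optimism" is the mean
of the z-scored reversal point and z-scored scaling asymmetry over the
units with both defined.

**Reliability.** Split-half consistency re-draws a random half-partition
*per neuron* on each of (default) 1,000 partitions, stratified by value
level × reward outcome so every estimator stays defined in both halves;
Pearson correlation across neurons per partition; summaries are the mean
r, the geometric mean of the p-values, and a bootstrap p defined as the
fraction of partitions with r ≤ 0 (the simplest sign-based summary
consistent with a 1/n_partitions resolution). A caveat the test-suite
documents explicitly: with a fixed dataset the two half-estimates sum to
the full-data value, so partitions are conditionally coupled and even a
noise population's mean r fluctuates dataset-to-dataset; the strict null
of the machinery is an estimator whose half-values are independent.
Anterior–posterior coordinates are min–max normalized within subject
before the topography correlation; subject-covariate controls use OLS
with subject indicator columns.

**Model comparison.** Four read-out models cross symmetric/asymmetric
learning with symmetric/asymmetric scaling; symmetric learning forces
α⁺ = α⁻ and symmetric scaling forces S = 0.5. Fitting is an exhaustive
grid search over {0, 0.025, …, 1}; β₀/β₁ by least squares at each grid
point. Implementation: the training R² at a grid point equals the squared
correlation between the scaled regressor and the rate, and the regressor
is linear in S for fixed (α⁺, α⁻), so the full R² surface is evaluated in
closed form from five moment statistics vectorised over the α grid — which
is what makes full-grid tenfold CV of whole populations run in seconds.
Ties resolve to the lexicographically smallest (α⁺, α⁻, S) via the flat
C-order argmax. Cross-validation uses contiguous trial blocks (the RPE
regressor depends on trial history; interleaved folds are available for
sensitivity checks); values are propagated over the full session with the
training-fitted parameters, avoiding arbitrary re-initialization at fold
boundaries, and held-out R² is computed on the test trials with β₀/β₁
refitted there by default (isolating the comparison to the asymmetry
structure; carrying them over is available and preserves the model
ranking). The fold count adapts downward with a warning on short
sessions. Parameter analyses (consistency, learning–scaling coupling) use
full grid fits on the two contiguous session halves, correlated across
neurons; cross-partition coupling correlates the learning asymmetry fitted
in one half with S fitted in the other, in both directions.

**Transitions.** Sign-switch trials are labelled on the best-fitting
model's δ trace (δ ≤ 0 counts as negative); for each switch the z-scored
rate at the switch trial is compared with the next encounter of the *same
cue* (value updates are cue-specific, so only that trial reflects the
update). The per-neuron contrast (−slope_pos) − (slope_neg) is a declared
convention — larger means faster decay of positive RPEs, i.e. more
optimistic learning. It is a deliberately coarse two-trial measure: even
noiseless coupled populations correlate with the fitted learning asymmetry
at r ≈ 0.75 rather than 1, and at rate noise of 0.5 × gain the correlation
attenuates toward zero; the tests exercise it at low noise.

**Expectile oracle.** Bisection on the monotone estimating function over
the sample range (deterministic, tolerance 10⁻¹⁰); the asymmetric-update
convergence check uses the time-average of V after burn-in, because the
fixed-α process fluctuates around the expectile rather than converging to
it.

## Problem sizes and reproducibility

Reference analyses use sessions of 600 trials and populations of 20–60
units — enough for every estimator to be well-defined while keeping whole
pipelines in seconds. The split-half machinery defaults to 1,000
partitions in the library, with smaller counts in the examples. All
randomness flows from a master seed through a fixed counter scheme
(`RunConfig.stage_seed`), so any stage can be re-run in isolation and
reports are byte-identical across runs.

## Known limitations

- The generator's rate noise is Gaussian and trial-independent; realistic
  spike-count noise (a Poisson option on the 0.4 s window) would lower
  effective SNR at low rates.
- The dynamic-task behavioural policy is not fitted to behaviour; analyses
  condition on the realized sequence.
- The transition-asymmetry contrast is a stand-in for a richer per-neuron
  learning measure and is noisy at realistic SNR (see above).
- Absolute held-out R² values depend entirely on the assumed noise level
  and are not meaningful outside a given simulation; only model rankings
  and parameter correlations are interpreted.
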