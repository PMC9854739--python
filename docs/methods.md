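# Methods

## Optimizer model

ADSCFGWO is a population metaheuristic over a bounded continuous cube,
always minimizing. Each iteration:

1. **Schedules.** The grey-wolf control parameter and the sine-cosine
   amplitude both decay linearly, `a(t) = r₁(t) = a_init·(1 − t/T_max)`
   with `a_init = 2`, so coefficient magnitudes shift from exploration
   (|A| can exceed 1) to exploitation as the run progresses. The symbol
   `r₁` plays two roles in the source formulation — a per-coefficient
   uniform draw inside `A = 2a·r₁ − a` and the deterministic SCA amplitude
   schedule; these are implemented as two distinct quantities, since each
   usage is individually standard and conflating them would break both
   updates.
2. **Stall detection.** If the best-so-far fitness is unchanged (relative
   tolerance 1e-12) over the last 3 recorded iterations, one agent is moved
   from exploitation to exploration. The trigger is evaluated once per
   iteration on the best-fitness history; the accumulated "boost" sits on
   top of a linear baseline schedule that decays the exploration share
   from 70% to 30% of the population, clamped to the [30%, 70%] caps. The
   boost can only raise the exploration count above the schedule, never
   push it below the floor.
3. **Group assignment.** Agents are ranked by fitness; the `n₂` best form
   the exploitation group (they refine good solutions), the `n₁` worst
   explore. `n₁ + n₂ = n` always.
4. **Moves.** Every agent takes a fitness-weighted grey-wolf step: the
   three leaders are collapsed into a weighted prey
   `w_α S_α + w_β S_β + w_δ S_δ` and a single distance `D` drives the
   three pull terms `Tᵢ = Sᵢ − Aᵢ·D`, averaged. A fresh uniform draw `r₄`
   then decides whether a sine-cosine perturbation is applied *to the
   grey-wolf candidate* (sequential composition, matching the order of the
   two update statements): sine for exploration agents when `r₄ < 0.5`,
   cosine for exploitation agents when `r₄ ≥ 0.5`.
5. **Clamping, evaluation, elitism.** Positions are clamped componentwise
   to the bounds and re-evaluated; non-finite fitness values are recorded
   as +∞ with a warning rather than raised. If no agent improves on the
   incumbent best, the incumbent replaces the worst agent, making the
   best-so-far sequence non-increasing by construction.

All randomness flows through one `numpy` generator seeded from the config;
identical (seed, config, objective) triples give bit-identical histories.
Repeated experiments derive run `k`'s seed as `seed + k`.

### Leader weights

The printed weight normalization divides each leader's raw fitness by the
sum of the three. Under minimization that hands the *worst* leader the
largest weight, contradicting the stated intent that exploitation should
refine the best solution. The default mode therefore normalizes
`1/(ε + f)` with `ε = 1e-12` so that the α leader dominates; the literal
normalization is retained as `weighting_mode="literal"` for comparison.
An all-zero denominator falls back to uniform weights with a degeneracy
flag. Negative fitness values (not produced by any objective shipped here)
are shifted to non-negative before inversion.

### Sine-cosine draw ranges

The configuration table declares `r₂, r₃ ∈ [0, 1]`, but the parent
algorithm draws the angle `r₂` from `[0, 2π]` and the target scale `r₃`
from `[0, 2]`. A sine restricted to `[0, 1]` radians is strictly positive
and biases every perturbation in one direction, so the standard ranges are
the default (`sca_r2_range="standard"`); the literal reading is available
as a switch. The parameter `C₂` appears in the source initialization but
in no equation; it is left unimplemented.

### Unspecified mechanics, resolved

Group membership (fitness-ranked), boundary handling (clamp), stall step
size (1 agent, cap at round(0.7·n), floor at round(0.3·n)), the 70→30
decay shape (linear), leader ties (stable index order), and elitism
mechanics (best-so-far replaces the worst agent on non-improving
iterations) are not specified by the source formulation; the choices above
were fixed once for reproducibility. Per-iteration complexity is O(n·d),
O(T_max·n·d) per run.

## Search space

Seven numeric training options are tunable; environment and reporting
options are constants carried through decoding. Axes (bounds centered on
the published defaults):

| axis | kind | bounds | default |
|---|---|---|---|
| InitialLearnRate | log-continuous | [1e-5, 1e-1] | 1e-4 |
| MiniBatchSize | categorical | {4, 8, 16, 32} | 8 |
| MaxEpochs | integer | [5, 30] | 20 |
| Momentum | continuous | [0.5, 0.99] | 0.9 |
| L2Regularization | log-continuous | [1e-6, 1e-2] | 1e-4 |
| RateDropFactor | continuous | [0.05, 0.5] | 0.1 |
| LearnRateDropPeriod | integer | [2, 20] | 10 |

Integer axes use a stratified floor map so every integer has equal
measure; categorical axes use equal-width bins; decode is monotone per
non-categorical axis and always produces a valid configuration.

## Fitness

The tuning objective is validation error, `1 − accuracy`, on the 20%
validation split of a 70/20/10 partition (seeded shuffle, contiguous
blocks, sizes rounded to sum to n). The split generator uses a seed
stream distinct from the phantom generator so that a dataset and a split
built from the same integer seed never share a permutation — sharing one
silently produces single-class validation sets. Evaluations are cached by
the decoded configuration; trainer divergence yields the worst fitness
(1.0) with a warning rather than an exception, keeping population updates
total.

Two deterministic trainer backends honor the full hyperparameter
vocabulary (minibatch SGD with momentum, L2 penalty, and a piecewise
schedule multiplying the rate by RateDropFactor every LearnRateDropPeriod
epochs):

* **linear** — logistic regression on pooled pixel features: 8×8 mean
  pooling, 8×8 max pooling, and three global intensity summaries (mean,
  max, top-1% mean). The max/summary channels make a small bright focal
  structure linearly detectable regardless of position. Default backend.
* **cnn** — a tiny convolutional network (two 3×3 conv blocks with 2×2
  max-pooling, dense sigmoid head) on inputs average-pooled to 32×32,
  epochs capped at 10. Exercises the same hyperparameters through a
  nonlinear model at a few hundred milliseconds per fit.

## Phantom data

The generator emulates the *label structure* of a tumor/normal MRI
classification task, not MRI physics: a smooth elliptical "brain"
(intensity 0.45 ± 0.05 low-frequency texture) on a dark background;
positive images add 1–3 bright elliptical lesions (offset +0.35, radius
3–8 px) wholly inside the brain mask; optional additive Gaussian noise;
pixels clipped to [0, 1]. Exactly round(n·tumor_fraction) images are
positive. At zero noise every lesion pixel is strictly brighter than any
pixel of any negative image, so the task is separable by construction —
passing tests demonstrate that the optimizer, trainers and statistics
interact correctly, not that any model would reach similar accuracy on
real MRI data, which has neither the controlled contrast nor the clean
labels of these phantoms.

Augmentation applies shift → flip → rotate(0–360°) → zoom(0.9–1.1) in that
fixed order (the order is otherwise unspecified), preserving image
dimensions, with bilinear interpolation and fill value 0 by default and a
nearest-neighbor mode for exactness tests; identity draws bypass the
interpolating warps so a zero transform is bit-exact. Labels are invariant
under augmentation.

## Statistics

* **Metrics.** The six standard ratios from TP/FP/TN/FN with label 1
  positive. Zero-denominator ratios are flagged NaN, never silently 0.
  `reconstruct_confusion` brute-forces the smallest integer margins whose
  rates round to printed values at a given decimal precision — a
  consistency oracle for published tables.
* **Descriptives.** Percentiles by linear interpolation between closest
  ranks (other conventions shift percentiles at n = 11); adjusted
  Fisher–Pearson skewness and sample-adjusted excess kurtosis, flagged
  NaN at zero SD; geometric/harmonic/quadratic means with back-transformed
  t-intervals, flagged for non-positive data. A constant vector reports
  SD exactly 0 (guarding against cancellation noise in the moment sums).
* **Median CI.** The order-statistic interval `(x₍k₎, x₍n+1−k₎)` with the
  largest k whose binomial coverage `1 − 2·P(Bin(n, ½) ≤ k−1)` still
  reaches the target; the discrete achieved coverage is reported (98.83%
  at n = 11), and an unreachable target returns the full range with a
  below-target flag.
* **ANOVA.** Classical one-way decomposition; `anova_from_summary`
  recovers the identical decomposition from printed group means/SDs with
  equal group sizes (`SS_b = n·Σ(mᵢ − m̄)²`, `SS_w = (n−1)·Σ sdᵢ²`). Zero
  within-group variance flags an infinite F.
* **Wilcoxon signed-rank.** Zero differences dropped (classical policy),
  midranks for ties. For n ≤ 25 the two-tailed p-value is exact:
  `P(W⁺ ≤ min(w⁺, w⁻)) + P(W⁺ ≥ max(w⁺, w⁻))` under the full null
  distribution of sign patterns, computed by convolution over
  doubled midranks (identical to enumerating all 2ⁿ patterns, and checked
  against a literal enumerator in the tests for n ≤ 12). Beyond n = 25 a
  tie-corrected normal approximation with continuity correction is used
  and flagged as such.

## Problem sizes

The shipped tests run the optimizer at 10 agents with iteration budgets
of 20–80 on 1–5 dimensional benchmarks, and the end-to-end tuning
experiment on 200 noiseless 64×64 phantoms with 10 agents, 20 iterations
and 11 seeded repeats using the linear backend — sizes chosen so the whole
suite completes in a few minutes on one CPU while still exercising every
mechanism at the published population and repeat counts.

## Known limitations

* The phantom task is linearly separable by design; optimizer gains over
  the corrupted baseline show sensitivity to hyperparameters, not
  clinical performance.
* The exact Wilcoxon implementation assumes the midrank convention; other
  zero/tie policies give different statistics.
* Percentiles, skewness and kurtosis at n = 11 are estimator-sensitive;
  published values computed under other conventions need not match
  digit-for-digit.
* The baselines are textbook GWO/SCA without restarts or parameter
  tuning; they are comparison scaffolding, not tuned competitors.
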