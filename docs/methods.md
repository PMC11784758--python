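# Methods

## The optimization model

`gmvonet` trains a small feed-forward classifier by *population search*
over its flattened weight vector rather than by backpropagation alone.
The search engine is the multi-verse optimizer (MVO) and a hybrid
variant (GMVO) that modulates MVO's exploitation step with a cheap
finite-difference estimate of the gradient direction.

A population of `n` candidate weight vectors ("universes") evolves for
`M` iterations inside a box `[lb, ub]^d`. Each iteration applies two
operators:

1. **White/black-hole exchange** (exploration). Fitness values are
   scaled to unit Euclidean norm, giving `F̃`. For each universe `i` and
   coordinate `j`, with probability `F̃_i` the coordinate is overwritten
   by the same coordinate of a donor row of the fitness-sorted
   population; the donor row is drawn by roulette-wheel selection with
   mass proportional to `(-F̃_sorted) - min + s` (`s = 1e-12`), so fitter
   rows donate more often. Poor universes are therefore rewritten
   aggressively while good ones are left mostly intact.

2. **Wormhole jump** (exploitation). With probability
   `P_w(m) = p_min + m (p_max - p_min)/M` each coordinate teleports to
   the neighbourhood of the elitist best:
   `x_ij = x_best_j ± v_T(m) * ((ub_j - lb_j) r4 + lb_j)`, where
   `v_T(m) = 1 - (m/M)^(1/chi)` shrinks from 1 to 0. Plain MVO chooses
   the sign with a fair coin (`r3`); the hybrid replaces `v_T` by
   `v_T * S_j` with

   `S_j = 1 + alpha * clip((x_best_j - x_worst_j + eps) / (2 dx_j), -c, c)`,

   where `dx_j` is drawn uniformly from `(1e-12, 1e-3]` per dimension
   per iteration, `x_worst` is the worst current universe, and
   `alpha = 0` recovers plain MVO exactly. The difference between the
   best and worst universes acts as a central-difference probe of the
   descent direction; dimensions where the population disagrees get
   larger steps, converged dimensions get `S ≈ 1`.

An elitist record of the best weight vector is kept outside the
population and never degraded, which makes the per-iteration best-so-far
history non-increasing by construction. All positions are clamped to the
box after every update.

### Why the gradient ratio is saturated (`grad_clip`, default 1)

The raw ratio `(x_best - x_worst)/(2 dx)` has magnitude of order
`|x_best - x_worst| / 1e-3`. Until the population has collapsed this is
10³–10⁹, which multiplies the wormhole step far past the box on every
jump; after clamping, every teleported coordinate lands exactly on a box
edge and the exploitation operator degenerates into corner sampling. In
that regime the elitist best measurably never improves (on the 10-d
sphere it stays at the initial-population value for 500 straight
iterations). Saturating the ratio at `±grad_clip` keeps
`S ∈ [1 - alpha, 1 + alpha]`, i.e. the adjusted traveling distance rate
is a bounded per-dimension modulation of the conventional schedule —
which is also the only regime in which the hybrid's published behaviour
(smooth convergence, adjusted-TDR curves tracking the conventional one)
is reproducible. `grad_clip=None` restores the unsaturated form for
experimentation.

### Draw-order contract

Reproducibility is defined by a documented order of draws from one PCG64
generator seeded by `OptimizerConfig.seed`:

1. initialisation: one `n × d` row-major uniform block mapped to the box;
2. per iteration: (a) the exchange `r1` block (`n × d`, row-major), then
   one roulette uniform per firing cell in row-major order; (b) for
   `alpha > 0` a length-`d` `dx` block; then the wormhole `r2` block
   (`n × d`, row-major), then per firing cell `(r3, r4)` pairs when
   `alpha = 0` or a single `r4` when `alpha > 0`.

Because the `dx` block is drawn only when `alpha > 0`, a hybrid run with
`alpha = 0` consumes the identical stream as plain MVO; the test suite
exploits this to check bitwise agreement with an independently written
nested-loop MVO over 10 iterations.

## The classifier

Three ReLU hidden layers and one sigmoid output unit; 9-5-3-2-1 for the
9-feature cytology table (79 parameters) and 17-8-4-2-1 for the
17-feature diagnostic table (193 parameters). The flat layout is, per
layer, the row-major `(fan_in × fan_out)` weight matrix followed by the
bias vector. The population fitness is the full-training-set mean
squared error between the sigmoid output and the 0/1 labels (cross-
entropy is available behind a switch); predictions threshold the output
probability at 0.5 with ties going to the positive (malignant) class.

The weight search box defaults to `[-10, 10]` per coordinate. The value
is a design choice (nothing in the problem pins it): it is wide enough
for the sigmoid and ReLU units to saturate where useful, and the
wormhole step scales with the box width so much wider boxes slow
exploitation.

## Gradient baselines

SGDM (heavy ball: `v ← μv + g`, `x ← x - ηv`) and ADAM (standard
bias-corrected moments) train the identical network through exact
backpropagation, with the study regime η = 1e-3, batch size 10, six
epochs, and seeded per-epoch shuffling. Unstated constants take the
conventional values μ = 0.9, β₁ = 0.9, β₂ = 0.999, ε = 1e-8. Their
default objective is binary cross-entropy — the conventional choice for
gradient-trained classifiers — while the population optimizers keep the
MSE fitness.

Initialization is He-normal with a +0.1 bias. With hidden layers as
narrow as 5/3/2 units on all-positive inputs, a zero-centred uniform
init regularly leaves an entire ReLU layer inactive, after which no
gradient flows at all; the positive bias largely removes that failure
mode, though at this learning rate and budget the baselines remain
seed-sensitive (which matches their reported behaviour: large spread,
occasional majority-class collapse).

## Data pipeline

The loader parses the two native UCI dialects (11 and 32 comma-separated
fields, `?` for the missing bare-nuclei cells) and validates the column
count. Cleaning drops the identifier, imputes missing bare nuclei with
the mean of the observed values, and maps labels to 0 = benign /
1 = malignant (`N` is accepted as a benign synonym alongside `B`). The
diagnostic table is reduced to a fixed, published list of 17 features;
the selection criterion behind that list is not re-derived here.

Imputation statistics are computed over the whole table before
splitting, mirroring the original order of steps; note this leaks a
small amount of test information into one feature's mean and can be
switched to train-only fitting by preprocessing after the split.
Min-max normalization to [0, 1] is fitted on the training split only
(the standard leakage-free protocol; a deliberate deviation from
normalizing before the split), constant features map to 0, and test
values outside the training range pass through unclipped. The 70/30
split is stratified and seeded; 10-fold cross-validation indices are
provided for validation protocols.

### What the synthetic generator emulates — and what it does not

`generate_synthetic` draws two Gaussian classes with exactly
`round(positive_fraction · n)` positives (default 241/699, the malignant
share of the original cytology table), per-feature class-mean gap
`separation · sigma` (defaults 2.0 and 1.5), and in ordinal mode rounds
and clips to the 1–10 cytology scale; it can inject missing cells into a
designated column and emit a raw table in the original dialect so the
whole loading path is exercised without a download. It emulates the
*structure* of the clinical tables (imbalance, ordinal scale,
missingness), not their difficulty: features are conditionally
independent and the classes are strongly separable, so classifiers
saturate near-perfect accuracy. Passing tests on this generator
demonstrate that the pipeline and optimizers work, not that the clinical
accuracy figures transfer; the optimizer ranking on near-saturated
synthetic data resolves only coarse differences (population methods vs.
under-trained gradient baselines), not the fine ordering between MVO and
its hybrid.

## Evaluation

The six metrics (accuracy, precision/PPV, specificity, sensitivity, F1,
MCC) are computed from the confusion matrix with 1 = malignant. Any
metric with a vanishing denominator is defined as 0 and flagged (the
usual MCC convention). Multi-run summaries report mean, best, worst and
the sample (R−1) standard deviation, plus mean wall time.

The Wilcoxon rank-sum test pools the two samples, assigns midranks to
ties (so `W1 + W2 = N(N+1)/2` identically), and decides two-sided: for
sizes up to 20 without ties it enumerates the exact null distribution of
the smaller sample's rank sum with a subset-sum dynamic program, taking
the critical value as the largest `c` with `P(W ≤ c) ≤ a/2`; with ties
or larger samples it uses the tie-corrected, continuity-corrected normal
approximation. The reported confidence level is `(1 − a)·100%`. Note
that published critical-value tables occasionally differ by one unit
from the strict not-exceeding convention (e.g. 84 vs 85 for sizes
(10, 12) at a = 0.05); this implementation follows the strict
convention and is cross-checked against `scipy.stats.mannwhitneyu`
exact p-values.

## Experiment harness

`run_comparison` executes `R` runs per optimizer with per-run seeds
`master_seed + i`, re-splitting the data each run (switchable),
summarizes each optimizer and compares accuracy vectors pairwise with
the rank-sum test; everything emitted is a pure function of the config.
Default hyperparameters follow the study regime: population 50,
M = 1000, `p_min = 0.5`, `p_max = 1`, `chi = 6`, `alpha = 0.7`;
η = 1e-3, batch 10, six epochs for the gradient baselines. For the
population optimizers "epochs" have no direct analogue, so each run's
loss history is checkpointed at six evenly spaced iterations as the
reporting granularity. `run_fraction_scaling` repeats the full cycle on
stratified subsamples (25–100% by default). Wall times are recorded but
never asserted on.

The benchmark sizes used by the test suite and the acceptance script —
10-d sphere with n = 50, M = 500 over 10 seeds; the synthetic
classification study with n = 500 samples, M = 1000, 10 repeats —
were chosen once as the package's standard problem sizes.

## Known limitations

- For symmetric boxes the random wormhole offset `((ub-lb) r4 + lb)` is
  sign-symmetric, so the *sign* of the gradient estimate cannot steer
  the search — only the per-dimension step magnitude adapts. The hybrid
  is therefore an adaptive-step MVO rather than a true descent method,
  and on saturated benchmarks it performs on par with plain MVO.
- The gradient baselines are deliberately run in the weak study regime
  (tiny net, 6 epochs, η = 1e-3); they are comparators, not tuned
  classifiers.
- The exact rank-sum path requires tie-free samples; accuracy vectors
  over repeated runs often contain ties, in which case the normal
  approximation is used even for small samples.
- The synthetic generator draws conditionally independent features; the
  real cytology/diagnostic features are strongly correlated.
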