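# Methods

## The capacity-bounded structure space

A structure is an ordered layer list over the alphabet {convolution with
kernel k ∈ kernel_set, max-pooling with window k ∈ pool_set, fully
connected}, terminated by one output layer whose width is the class
count.  During enumeration every conv and hidden dense layer has the same
fixed width (default 10).  Spatial bookkeeping: images are square;
convolutions use same padding at stride 1 (extent preserved, channels set
to the layer width); pooling uses stride equal to its window with same
padding, so an n-pixel extent becomes ceil(n/k), and a window larger than
the current extent is not offered; dense layers flatten whatever they
receive (`n·n·channels` for an unflattened input — for a dense first
layer that is the raw image).  Convolutions and pooling may not follow a
dense layer.

Weights including biases: `k·k·c_in·c_out + c_out` per convolution,
`d_in·d_out + d_out` per dense layer, zero for pooling.  The admissibility
score of a layer prefix is the capacity bound of the prefix *with the
output layer appended*, so every tree node is judged as a complete
network.

**Concretizing the bound.**  For piecewise-linear networks the
near-tight VC-dimension upper bound is proportional to `W·L·log W`, with
`W` the total weight count and `L` the number of weight-bearing layers.
A proportionality constant and a logarithm base must be pinned to make it
a computable admission rule; this package uses constant 1 and base 2
(`vc = W·L·log₂W`), with the base configurable.  Supporting evidence for
base 2: the best-known reference structures for the 28×28 (10-class,
budget 3.5 M) and 64×64 (2-class, budget 2.725 M) geometries evaluate to
92.4 % and 94.0 % of their budgets under base 2 — just admissible, as a
structure found by exhaustive search under the budget should be — while
under base e they sit at only ~65 %.

**Emission rule.**  Every admissible prefix — including the empty one —
contributes one structure (prefix + output layer); a `leaf_only` mode
that emits only prefixes with no admissible extension is available for
comparison.  The space is therefore exactly the set of all valid layer
sequences whose capacity bound fits the budget, which is what the
brute-force oracle in the test suite enumerates independently.

**Tree walk and pruning.**  Children are expanded in a canonical order
(conv by ascending kernel, pooling by ascending window, dense), making
enumeration deterministic.  Because pooling carries no weights but
shrinks the output layer's input, a prefix that is over budget can still
have admissible descendants; branches are pruned only when an optimistic
lower bound on any completion — maximal pooling, then the cheapest
possible output connection — already exceeds the budget.  This bound also
guarantees termination, so no depth cap is needed; `max_depth` (default
512) exists purely as a runaway-recursion guard and never truncates a
real space.  `count_structures` computes exact counts by dynamic
programming over collapsed prefix states (spatial extent, channels/units,
W, L); its agreement with the materializing enumerator is property-tested
against the brute-force oracle on randomized small spaces.

**Calibration.**  `vcnas calibrate` sizes the three study geometries
under every combination of log base (2, e, 10) and emission rule.  Under
the pinned configuration the spaces contain 4,074,152 / 3,632,372 /
3,910,961 structures (28×28×1 @ 3.5 M, 32×32×3 @ 3.5 M, 64×64×3 @
2.725 M).  Historical reference counts in the low thousands have been
reported for these same geometries and budgets; no configuration in the
sweep reproduces them, and our analysis (including many further rule
variants: kernel-extent limits, pooling divisibility, consecutive-pool
bans, depth caps, alternative weight accounting) indicates they reflect
additional admissibility constraints that were never stated.  The sweep
documents this openly rather than hard-coding a matching rule we cannot
justify.

## Training protocol

The search compares structures, so the protocol is held fixed: Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at a constant learning rate of 0.001, no
weight decay, softmax cross-entropy, minibatches of a configured size
(last partial batch kept — `ceil(n/batch)` iterations per epoch), one
validation pass after every epoch.  Early stopping: training halts when
the last five epochs (configurable patience) produced no new strict
minimum of the validation error; the score of a trial is the curve
minimum, ties resolving to the earliest epoch.  `max_epochs` (default
200) is a safety cap only.

Models realize a structure with ReLU after every conv and hidden dense
layer — the capacity bound assumes piecewise-linear activations — and no
activation on the output (softmax lives in the loss).  Weights are He
initialized from the trial seed; minibatch order is drawn from the same
seeded generator, so a (structure, data, config, seed) tuple reproduces
its validation curve bit-for-bit.  A diverged trial (non-finite loss) is
recorded as a failed trial with error 1.0 instead of raising, so a grid
run survives pathological corners of the space.  The implementation is
plain NumPy (shift-and-accumulate convolutions, argmax-routed pooling
gradients, dense layers as matrix products); backward passes are verified
against centered finite differences in the test suite.

## The two-step search

Step 1 trains every structure once per constant width (default 10, 20,
40, 80; the replicates remove bias toward any single fixed dimension) and
scores a structure by the minimum of its best validation errors across
widths (`mean` is selectable).  Ties break toward lower VC-dimension,
then canonical encoding.  The five lowest-error structures advance.
Step 2 trains every assignment of the width option set to each advanced
structure's conv and hidden dense layers (`|options|^(width-bearing
layers)` trials per structure; the output width stays at the class
count), and merges all trials into one ascending ranking, ties breaking
toward fewer total weights — prefer the cheaper network at equal error.
`improvement_over_average = mean(score) − min(score)` in percentage
points summarizes each step.  Held-out test evaluation is a separate,
explicit call (`evaluate_test`) and never informs either ranking.

Every trial is appended to a JSONL ledger keyed by a hash of the
structure encoding, protocol parameters and step tag; re-running a search
over an existing ledger trains nothing and reproduces the report exactly,
which is also how an interrupted grid resumes.

## Synthetic data

The generator renders each class as a deterministic template of one or
two anisotropic Gaussian bumps (position, scale, orientation drawn from a
class-keyed generator), modulated per channel, with per-sample spatial
jitter (default 3 % of the image extent) and i.i.d. additive pixel noise
(`noise_sd`), clipped to [0, 1].  Class imbalance is set by per-class
counts (e.g. 1:2 to emulate a positive/negative pathology patch ratio).
With `noise_sd = 0` the classes are cleanly learnable: a minimal
conv–pool–dense model reaches zero training error within a few dozen
epochs, which the tests assert.  What the generator does *not* emulate:
intra-class shape variation beyond jitter, staining/illumination
variation, label noise, or background clutter of real histology patches
— so passing tests demonstrate the machinery (enumeration, protocol,
ranking, resume, analytics) at study scale, not clinical performance.

Subsampling splits are uniform without replacement from a seeded
generator (stratification available, off by default), reproducing the
fixed train/validation sizes used at each study scale (800/200, 400/100,
60/40, 2500/800/990).

## Analytics

Error histograms use left-closed right-open 2 % bins over [0, 100].
Box-whisker summaries per structural attribute use linear-interpolation
quartiles and Tukey whiskers (most extreme observations within 1.5·IQR of
the quartiles).  VC-dimension is binned into 10 log-spaced bins between
the observed extremes by default; the small integer attributes (depth,
layer counts) get one bin per value.  Both are pure functions of the
ledger.

## Problem sizes in the test suite

The full grids behind the study-scale geometries (thousands of structures
× four widths on real datasets) are cluster-scale; the suite instead
exercises every mechanism at desk scale as the package's own choice of
problem size: a 59-structure space (12×12×1, budget 16,000, kernels
{3,5}, pool {2}), 300 train / 100 validation synthetic images, step-1
widths {8, 16} and step-2 options {16, 32}, three seeds.  On this scale
the search reliably returns a network at ≤ 10 % validation error with a
positive improvement over the space average.  Oracle-equivalence tests
run 20 randomized configurations capped at 500 structures and depth 6.

## Known limitations

- The VC bound is an order-of-magnitude admission rule, not a tight
  capacity estimate; different pinnings rescale the space monotonically.
- One seed per trial by default; small validation sets (e.g. 40 samples)
  make ranking ties likely, and the deterministic tie-breaks are a
  convention, not a statistical resolution.
- No learning-rate schedules, regularization, augmentation or cross-
  validation — deliberately, so that structure is the only moving part.
- The NumPy trainer targets small images and widths; it is single-core
  and not suited to ImageNet-scale work.
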