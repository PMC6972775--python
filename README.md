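# vcnas — CNN structure search under a VC-dimension budget

Deep networks are usually grown by stacking layers, on the assumption that
more data will keep overfitting at bay.  Small-sample image classification
— a few hundred to a few thousand labelled images, the common situation in
medical imaging (MRI, ultrasound, histopathology mitosis patches) — breaks
that assumption: the best network is often small, and *which* small
structure wins depends on the data itself.  `vcnas` is a tool for finding
it exhaustively rather than by rule of thumb.

## What it does

**Enumerate.**  Every structure built from convolutions (kernels 5×5/7×7
by default, same padding), max-pooling (2×2/4×4 windows, stride = window)
and fully-connected layers, ending in an output layer, is admitted into
the search space when an upper bound on its Vapnik–Chervonenkis dimension
fits a budget:

```
VCDim ≤ W · L · log₂ W ≤ max_vc
```

with `W` the total weight count including biases (`k·k·c_in·c_out + c_out`
per convolution, `d_in·d_out + d_out` per dense layer; pooling is
weight-free but shrinks later dense inputs) and `L` the number of
weight-bearing layers.  The space is generated by a deterministic tree
walk and is exactly the set of all layer sequences under the budget.

**Search in two steps.**  Step 1 trains every structure at a few constant
layer widths under a fixed protocol — Adam, learning rate 0.001, no weight
decay, softmax cross-entropy, validation after every epoch, early stopping
after five epochs without a new minimum — and ranks structures by their
best validation error.  Step 2 takes the five best structures, trains
every assignment of a width option set (e.g. 32/64/128) to their layers,
and re-ranks.  The report records both rankings and the improvement of the
best network over the average one, in percentage points of error.

**Analyze.**  Error histograms (2% bins) and box-whisker summaries of
error against VC-dimension, depth and per-type layer counts show which
structural hyperparameters the data actually cares about.

Data comes in as MNIST-style IDX files, CIFAR-10 binary batches, labelled
PNG/TIFF patch folders with a CSV manifest, or a seeded synthetic
generator of blob-motif classes that makes the whole pipeline runnable
without downloads.

## Worked example

`python examples/two_step_search_synthetic.py` enumerates 59 structures
for a 12×12×1 geometry (budget 16,000), searches them on 300 training /
100 validation synthetic images, and prints:

```
step 1 (structures at constant widths), five best:
  0.000  Conv3 → MP2 → MP2 → MP2 → Full
  0.000  MP2 → Conv3 → MP2 → MP2 → Full
  0.000  Conv5 → MP2 → MP2 → MP2 → MP2 → Full
  0.000  Conv3 → MP2 → MP2 → Full
  0.000  Conv5 → MP2 → MP2 → Full
step 1 improvement over the average structure: 35.49 points

step 2 (width permutations of the top five), five best:
  0.000  Conv3,16 → MP2 → MP2 → MP2 → Full,3
  ...
step 2 improvement over the average permutation: 14.90 points

selected network: Conv3,16 → MP2 → MP2 → MP2 → Full,3
```

Reading: the best structure classifies the validation set perfectly while
the average structure in the same space is ~35 points worse — on small
samples the structure choice matters far more than width (the width step
adds ~15 points over a random width assignment of an already-good
structure).  Structure strings follow the `Conv5 → MP2 → Full` notation;
a `,width` suffix gives a layer's channels/units.

Other examples: `enumerate_space.py` (spaces and their sizes),
`train_one_structure.py` (one training run and its validation curve),
`ledger_analytics.py` (histogram and box-whisker tables).

## Command line

```bash
vcnas enumerate --input 28x28x1 --classes 10 --max-vc 3500000 --count-only
vcnas synth --classes 3 --per-class 140 --size 12 --seed 7 --out data.npz
vcnas run config.yaml              # enumerate -> step1 -> step2 -> analyze
vcnas run config.yaml --only step1 # stages are idempotent via the ledger
vcnas calibrate                    # space sizes under each bound concretization
```

`vcnas run` reads a YAML config (dataset, enumeration, training, search
blocks; see `tests/test_cli.py` for a complete one), writes
`structures.jsonl`, a `ledger.jsonl` of every trained network, a
`report.json` and analytics CSVs, and re-runs resume from the ledger
without retraining.

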