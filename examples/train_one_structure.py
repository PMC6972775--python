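"""Train a single structure under the fixed small-sample protocol.

Generates seeded synthetic motif classes, splits them 300 train / 100
validation, trains one conv-pool-dense structure with Adam (lr 0.001,
patience-5 early stopping) and prints the per-epoch validation error
curve that the search steps use as their ranking score.
"""

from vcnas import (
    EnumerationConfig,
    SplitSpec,
    TensorShape,
    TrainConfig,
    decode_structure,
    generate_synthetic,
    subsample_split,
    train_model,
)

bundle = generate_synthetic(3, 150, size=12, channels=1, noise_sd=0.05, seed=7)
train, val, _ = subsample_split(bundle, SplitSpec(300, 100, seed=1))

config = EnumerationConfig(TensorShape(12, 12, 1), 3, max_vc=1e9)
structure = decode_structure("Conv5 → MP2 → Full → Full", config)

result = train_model(structure, train, val, TrainConfig(batch_size=100, seed=0))
print(f"structure:      {result.structure_encoding}")
print(f"epochs trained: {len(result.val_error_curve)} "
      f"(early stop: {result.stopped_early})")
print("validation error curve:",
      " ".join(f"{e:.2f}" for e in result.val_error_curve))
print(f"best epoch {result.best_epoch}, best validation error "
      f"{result.best_val_error:.3f}")

# The minimum of the curve is this network's score; training halts once
# five consecutive epochs fail to improve on it.
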