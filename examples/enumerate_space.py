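"""Enumerate a structure space under a VC-dimension budget.

Builds the space of all conv/pool/dense structures for a small 12x12
grayscale geometry, prints a few of them with their capacity numbers, and
then sizes the three study geometries (28x28x1, 32x32x3, 64x64x3) without
materializing their multi-million-structure spaces.
"""

from vcnas import EnumerationConfig, TensorShape, enumerate_structures
from vcnas.arch_space import count_structures

config = EnumerationConfig(
    TensorShape(12, 12, 1), n_classes=3, max_vc=16_000,
    kernel_set=(3, 5), pool_set=(2,), fixed_width=10,
)
structures = enumerate_structures(config)
print(f"{len(structures)} structures fit a VC budget of {config.max_vc:,.0f}:")
for s in structures[:5]:
    print(f"  {s.encoding:<40} W={s.total_weights:<6} L={s.weighted_layer_count} "
          f"VC={s.vc_dimension:,.0f}")
print("  ...")

for name, shape, classes, budget in [
    ("28x28x1 /10 classes", TensorShape(28, 28, 1), 10, 3_500_000),
    ("32x32x3 /10 classes", TensorShape(32, 32, 3), 10, 3_500_000),
    ("64x64x3 / 2 classes", TensorShape(64, 64, 3), 2, 2_725_000),
]:
    n = count_structures(EnumerationConfig(shape, classes, budget))
    print(f"{name}, budget {budget:,}: {n:,} structures")

# Every structure printed above is small enough that a few hundred labelled
# images can constrain all its weights; the budget is what keeps the space
# trainable in the small-sample regime.
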