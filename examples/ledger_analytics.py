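"""Error histogram and structural box-whisker statistics from a ranking.

Runs a quick structure step over a small space, then summarizes the
resulting errors the way the search results are analyzed: a 2%-bin error
histogram, and five-number summaries of error against VC-dimension and
depth.
"""

import pandas as pd

from vcnas import (
    EnumerationConfig,
    SplitSpec,
    TensorShape,
    TrainConfig,
    attribute_boxstats,
    enumerate_structures,
    error_histogram,
    generate_synthetic,
    run_structure_step,
    subsample_split,
)

space = EnumerationConfig(
    TensorShape(12, 12, 1), 3, max_vc=12_000, kernel_set=(3,), pool_set=(2,)
)
structures = enumerate_structures(space)
bundle = generate_synthetic(3, 150, size=12, channels=1, noise_sd=0.05, seed=7)
train, val, _ = subsample_split(bundle, SplitSpec(300, 100, seed=1))

ranking = run_structure_step(
    structures, train, val, TrainConfig(batch_size=100, seed=0, max_epochs=25),
    widths=(8,),
)

frame = pd.DataFrame(
    {
        "error": [score for _, score in ranking],
        "vc_dimension": [s.vc_dimension for s, _ in ranking],
        "depth": [s.depth for s, _ in ranking],
        "n_conv": [s.n_conv for s, _ in ranking],
        "n_dense": [s.n_dense for s, _ in ranking],
        "n_maxpool": [s.n_maxpool for s, _ in ranking],
    }
)

hist = error_histogram(frame["error"])
print("error histogram (2% bins, non-empty only):")
print(hist[hist["count"] > 0].to_string(index=False))

for attribute in ("vc_dimension", "depth"):
    stats = attribute_boxstats(frame, attribute, n_bins=4)
    print(f"\nerror vs {attribute} (bin medians):")
    t = stats.table
    print(t[t["count"] > 0][["bin_left", "bin_right", "count", "median"]]
          .to_string(index=False))
    print(f"overall best error falls in bin {stats.global_min_bin}")

# A flat median across bins would say the attribute barely matters; a
# sloped one locates the capacity regime the data prefers.
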