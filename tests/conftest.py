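import itertools

import numpy as np
import pytest

from vcnas import (
    EnumerationConfig,
    NetworkStructure,
    SplitSpec,
    TensorShape,
    generate_synthetic,
    propagate_shape,
    structure_vc,
    subsample_split,
)
from vcnas.arch_space import CONV, DENSE, MAXPOOL, LayerSpec


@pytest.fixture(scope="session")
def mnist_like_config():
    """The 28x28 grayscale geometry with the study's capacity budget."""
    return EnumerationConfig(TensorShape(28, 28, 1), 10, 3_500_000)


@pytest.fixture(scope="session")
def tiny_config():
    """A small space (hundreds of structures) for exhaustive checks."""
    return EnumerationConfig(
        TensorShape(8, 8, 1), 2, 6_000, kernel_set=(3,), pool_set=(2,), fixed_width=2
    )


@pytest.fixture(scope="session")
def separable_data():
    """Noise-free synthetic motif classes split 300 train / 100 val."""
    bundle = generate_synthetic(3, 150, size=12, channels=1, noise_sd=0.0, seed=7)
    train, val, _ = subsample_split(bundle, SplitSpec(300, 100, 0, seed=1))
    return train, val


def brute_force_structures(config: EnumerationConfig, max_len: int) -> set[str]:
    """Independent oracle: try every layer sequence up to ``max_len``.

    Enumerates the raw product of the layer alphabet, keeps topologically
    valid sequences, and filters by the capacity bound of the sequence with
    the output layer appended.  Shares no code with the tree recursion.
    """
    alphabet = [LayerSpec(CONV, size=k, width=config.fixed_width) for k in config.kernel_set]
    alphabet += [LayerSpec(MAXPOOL, size=k) for k in config.pool_set]
    alphabet += [LayerSpec(DENSE, width=config.fixed_width)]
    found: set[str] = set()
    for length in range(max_len + 1):
        for seq in itertools.product(alphabet, repeat=length):
            shape = config.input_shape
            valid = True
            for layer in seq:
                try:
                    shape = propagate_shape(shape, layer)
                except ValueError:
                    valid = False
                    break
            if not valid:
                continue
            if structure_vc(seq, config) <= config.max_vc:
                structure = NetworkStructure(
                    tuple(seq) + (config.output_layer,),
                    config.input_shape,
                    config.log_base,
                )
                found.add(structure.encoding)
    return found


def random_tiny_configs(n_configs: int, seed: int = 2024, max_count: int = 500):
    """Seeded sample of small enumeration configs, each with a shallow,
    fully brute-forceable space (depth well under the oracle cap)."""
    rng = np.random.default_rng(seed)
    configs = []
    while len(configs) < n_configs:
        size = int(rng.choice([6, 8, 9, 12]))
        channels = int(rng.choice([1, 3]))
        classes = int(rng.choice([2, 3]))
        kernels = tuple(
            sorted(rng.choice([2, 3, 5], size=rng.integers(1, 3), replace=False))
        )
        pools = (int(rng.choice([2, 3])),)
        width = int(rng.choice([3, 4, 6]))
        shape = TensorShape(size, size, channels)
        base = structure_vc((), EnumerationConfig(shape, classes, 1.0, kernels, pools, width))
        cap = base * float(rng.uniform(1.5, 12.0))
        from vcnas.arch_space import count_structures

        from vcnas.arch_space import enumerate_structures

        config = EnumerationConfig(shape, classes, cap, kernels, pools, width)
        for _ in range(8):  # shrink until small and shallow enough to brute-force
            count = count_structures(config)
            if 0 < count <= max_count:
                structures = enumerate_structures(config)
                if max(s.depth for s in structures) <= 6:
                    configs.append(config)
                    break
            config = EnumerationConfig(
                shape, classes, config.max_vc * 0.55, kernels, pools, width
            )
    return configs
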