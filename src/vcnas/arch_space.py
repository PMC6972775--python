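"""Network structure space: layer accounting, VC-dimension bound, enumeration.

This module defines the combinatorial search space of small convolutional
network structures.  A *structure* is an ordered list of layers
(convolution, max-pooling, fully-connected) terminated by a single output
layer, built over a fixed layer width.  Structures are admitted into the
space when an upper bound on their Vapnik-Chervonenkis dimension —
``VC(W, L) = W * L * log(W)`` with ``W`` the total number of weights
(including biases) and ``L`` the number of weight-bearing layers — does not
exceed a configured budget.  Capacity control of this form keeps every
candidate network small enough to be trainable from a few hundred samples.

The enumeration is a depth-first tree walk: each tree node is a valid layer
prefix, each admissible node contributes one structure (the prefix with the
output layer appended), and children are expanded in a canonical order so
that the output is deterministic.

Weight accounting follows the standard parameter-count formulas:

* convolution, kernel ``k``, ``c_in -> c_out`` channels:
  ``k * k * c_in * c_out + c_out``
* fully-connected, ``d_in -> d_out`` units: ``d_in * d_out + d_out``
* max-pooling layers carry no weights but shrink the spatial extent and
  thereby the input dimension of any later fully-connected layer.

All windowed operations use "same" zero padding; pooling with window ``k``
uses stride ``k``, so an ``n`` pixel extent becomes ``ceil(n / k)``.
"""

from __future__ import annotations

import itertools
import json
import math
import sys
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "LayerSpec",
    "TensorShape",
    "NetworkStructure",
    "EnumerationConfig",
    "TopologyError",
    "GeometryError",
    "StructureParseError",
    "conv_weight_count",
    "dense_weight_count",
    "propagate_shape",
    "vc_dimension",
    "structure_vc",
    "enumerate_structures",
    "iter_structures",
    "count_structures",
    "permute_widths",
    "encode_structure",
    "decode_structure",
    "calibration_sweep",
    "structure_record",
    "write_structures_jsonl",
    "read_structures_jsonl",
]

CONV = "conv"
MAXPOOL = "maxpool"
DENSE = "dense"
OUTPUT = "output"

_WEIGHTED_KINDS = frozenset({CONV, DENSE, OUTPUT})


class TopologyError(ValueError):
    """A layer sequence violates ordering rules (e.g. conv after flatten)."""


class GeometryError(ValueError):
    """A windowed operation does not fit the current spatial extent."""


class StructureParseError(ValueError):
    """A structure string does not match the encoding grammar."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at layer position {position})")
        self.position = position


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a network structure.

    Parameters
    ----------
    kind
        ``"conv"``, ``"maxpool"``, ``"dense"`` or ``"output"``.
    size
        Square kernel extent for conv, window extent for maxpool.
        Must be absent for dense/output layers.
    width
        Output channels (conv) or output units (dense/output).
        Must be absent for maxpool layers, which carry no weights.
    """

    kind: str
    size: int | None = None
    width: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in (CONV, MAXPOOL, DENSE, OUTPUT):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in (CONV, MAXPOOL):
            if self.size is None or self.size < 1:
                raise ValueError(f"{self.kind} layer needs a positive size")
        elif self.size is not None:
            raise ValueError(f"{self.kind} layer takes no size")
        if self.kind == MAXPOOL:
            if self.width is not None:
                raise ValueError("maxpool layer has no width")
        elif self.width is None or self.width < 1:
            raise ValueError(f"{self.kind} layer needs a positive width")

    @property
    def has_weights(self) -> bool:
        return self.kind in _WEIGHTED_KINDS


@dataclass(frozen=True)
class TensorShape:
    """Shape of the data tensor between layers.

    Spatial extents are square (``height == width``) throughout.  Once a
    dense layer has been applied the tensor is flattened: the unit count is
    stored in ``channels`` and the spatial extents collapse to 1.
    """

    height: int
    width: int
    channels: int
    flattened: bool = False

    def __post_init__(self) -> None:
        if self.height != self.width:
            raise ValueError("images are square: height must equal width")
        if min(self.height, self.width, self.channels) < 1:
            raise ValueError("shape extents must be positive")

    @property
    def flat_dim(self) -> int:
        """Input dimensionality seen by a fully-connected layer."""
        return self.height * self.width * self.channels


def conv_weight_count(k: int, in_ch: int, out_ch: int) -> int:
    """Weights (incl. bias) of a conv layer: ``k*k*in_ch*out_ch + out_ch``."""
    if min(k, in_ch, out_ch) < 1:
        raise ValueError("conv weight count needs positive arguments")
    return k * k * in_ch * out_ch + out_ch


def dense_weight_count(in_dim: int, out_dim: int) -> int:
    """Weights (incl. bias) of a dense layer: ``in_dim*out_dim + out_dim``."""
    if min(in_dim, out_dim) < 1:
        raise ValueError("dense weight count needs positive arguments")
    return in_dim * out_dim + out_dim


def propagate_shape(shape: TensorShape, layer: LayerSpec) -> TensorShape:
    """Shape of the tensor after applying ``layer`` to ``shape``.

    Convolutions use same padding (spatial extent preserved); pooling with
    window ``k`` uses stride ``k`` and same padding, giving ``ceil(n/k)``;
    dense layers flatten whatever they receive.
    """
    if shape.flattened and layer.kind in (CONV, MAXPOOL):
        raise TopologyError(f"{layer.kind} layer cannot follow a dense layer")
    if layer.kind == CONV:
        return TensorShape(shape.height, shape.width, layer.width)
    if layer.kind == MAXPOOL:
        if layer.size > shape.height:
            raise GeometryError(
                f"pool window {layer.size} exceeds spatial extent {shape.height}"
            )
        n = math.ceil(shape.height / layer.size)
        return TensorShape(n, n, shape.channels)
    # dense / output
    return TensorShape(1, 1, layer.width, flattened=True)


def vc_dimension(total_weights: int, weighted_layers: int, log_base: float = 2.0) -> float:
    """Capacity bound ``W * L * log(W)`` for a piecewise-linear network.

    The bound is stated up to a constant; this concretization uses constant 1
    and a configurable logarithm base (default 2).  ``W == 0`` returns 0 by
    convention.
    """
    if total_weights < 0 or weighted_layers < 0:
        raise ValueError("weight and layer counts must be non-negative")
    if total_weights == 0:
        return 0.0
    return total_weights * weighted_layers * math.log(total_weights, log_base)


def _accounting(layers: Sequence[LayerSpec], input_shape: TensorShape):
    """Walk ``layers`` from ``input_shape``; return (W, L, final_shape)."""
    shape = input_shape
    total = 0
    weighted = 0
    for layer in layers:
        if layer.kind == CONV:
            total += conv_weight_count(layer.size, shape.channels, layer.width)
        elif layer.kind in (DENSE, OUTPUT):
            total += dense_weight_count(shape.flat_dim, layer.width)
        if layer.has_weights:
            weighted += 1
        shape = propagate_shape(shape, layer)
    return total, weighted, shape


@dataclass(frozen=True)
class NetworkStructure:
    """A complete structure: layer list ending in exactly one output layer.

    Derived totals (weights, weighted-layer count, VC-dimension, per-type
    counts) are computed once from the propagated shapes and frozen.
    """

    layers: tuple[LayerSpec, ...]
    input_shape: TensorShape
    log_base: float = 2.0
    total_weights: int = field(init=False, default=0)
    weighted_layer_count: int = field(init=False, default=0)
    vc_dimension: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if not self.layers or self.layers[-1].kind != OUTPUT:
            raise TopologyError("structure must end with exactly one output layer")
        if any(l.kind == OUTPUT for l in self.layers[:-1]):
            raise TopologyError("output layer must be terminal and unique")
        w, l, _ = _accounting(self.layers, self.input_shape)
        object.__setattr__(self, "total_weights", w)
        object.__setattr__(self, "weighted_layer_count", l)
        object.__setattr__(self, "vc_dimension", vc_dimension(w, l, self.log_base))

    @property
    def depth(self) -> int:
        """Number of non-output layers."""
        return len(self.layers) - 1

    @property
    def n_conv(self) -> int:
        return sum(1 for l in self.layers if l.kind == CONV)

    @property
    def n_dense(self) -> int:
        """Hidden dense layers (the output layer is counted separately)."""
        return sum(1 for l in self.layers if l.kind == DENSE)

    @property
    def n_maxpool(self) -> int:
        return sum(1 for l in self.layers if l.kind == MAXPOOL)

    @property
    def n_classes(self) -> int:
        return self.layers[-1].width

    @property
    def encoding(self) -> str:
        return encode_structure(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.encoding


@dataclass(frozen=True)
class EnumerationConfig:
    """Geometry, layer alphabets and capacity budget for enumeration.

    ``fixed_width`` is the constant channel/unit dimension given to every
    conv and hidden dense layer during the structure step; the output layer
    always has ``n_classes`` units.  ``max_depth`` is a runaway-recursion
    guard only — the VC budget is what terminates every branch.
    """

    input_shape: TensorShape
    n_classes: int
    max_vc: float
    kernel_set: tuple[int, ...] = (5, 7)
    pool_set: tuple[int, ...] = (2, 4)
    fixed_width: int = 10
    log_base: float = 2.0
    emission: str = "every_node"
    max_depth: int = 512

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernel_set", tuple(sorted(set(self.kernel_set))))
        object.__setattr__(self, "pool_set", tuple(sorted(set(self.pool_set))))
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.fixed_width < 1:
            raise ValueError("fixed_width must be positive")
        if self.emission not in ("every_node", "leaf_only"):
            raise ValueError("emission must be 'every_node' or 'leaf_only'")
        if any(k < 1 for k in self.kernel_set + self.pool_set):
            raise ValueError("kernel and pool extents must be positive")
        if self.max_vc <= 0:
            raise ValueError("max_vc must be positive")

    @property
    def output_layer(self) -> LayerSpec:
        return LayerSpec(OUTPUT, width=self.n_classes)


def structure_vc(layers: Sequence[LayerSpec], config: EnumerationConfig) -> float:
    """VC bound of a layer prefix with the output layer appended.

    This is the admissibility value tested against ``config.max_vc``: every
    tree node is judged as if it were completed into a network right there.
    """
    w, l, shape = _accounting(layers, config.input_shape)
    w += dense_weight_count(shape.flat_dim, config.n_classes)
    return vc_dimension(w, l + 1, config.log_base)


def _children(config: EnumerationConfig, shape: TensorShape) -> Iterator[LayerSpec]:
    """Candidate next layers for a prefix ending at ``shape``, canonical order:
    conv (ascending kernel), maxpool (ascending window), dense."""
    if not shape.flattened:
        for k in config.kernel_set:
            yield LayerSpec(CONV, size=k, width=config.fixed_width)
        for k in config.pool_set:
            if k <= shape.height:
                yield LayerSpec(MAXPOOL, size=k)
    yield LayerSpec(DENSE, width=config.fixed_width)


def _child_state(shape: TensorShape, w: int, l: int, layer: LayerSpec):
    if layer.kind == CONV:
        dw = conv_weight_count(layer.size, shape.channels, layer.width)
    elif layer.kind == DENSE:
        dw = dense_weight_count(shape.flat_dim, layer.width)
    else:
        dw = 0
    return propagate_shape(shape, layer), w + dw, l + (1 if layer.has_weights else 0)


def _admissible(config: EnumerationConfig, shape: TensorShape, w: int, l: int) -> bool:
    wt = w + dense_weight_count(shape.flat_dim, config.n_classes)
    return vc_dimension(wt, l + 1, config.log_base) <= config.max_vc


def _min_spatial(n: int, pool_set: tuple[int, ...]) -> int:
    """Smallest spatial extent reachable from ``n`` by admissible pooling."""
    best = n
    frontier = {n}
    while frontier:
        nxt = set()
        for cur in frontier:
            for k in pool_set:
                if k <= cur:
                    out = math.ceil(cur / k)
                    if out < best:
                        best = out
                    if out < cur:
                        nxt.add(out)
        frontier = nxt
    return best


def _explorable(config: EnumerationConfig, shape: TensorShape, w: int, l: int) -> bool:
    """Can any continuation of this prefix still meet the budget?

    Pooling carries no weights but shrinks the output layer's input, so a
    prefix over budget may have admissible descendants.  This optimistic
    bound uses the smallest reachable flattened dimension: if even the
    cheapest completion (maximal pooling, then either the output layer
    directly or one fixed-width dense then the output) exceeds ``max_vc``,
    no descendant can be admissible and the branch is pruned.
    """
    if _admissible(config, shape, w, l):
        return True
    if shape.flattened:
        return False  # only dense extensions remain; W and L only grow
    min_sp = _min_spatial(shape.height, config.pool_set)
    # cheapest conceivable output-layer input over all continuations:
    # maximal pooling (channels unchanged or reduced to fixed_width by a
    # conv), or a fixed-width dense directly feeding the output layer
    min_in = min(min_sp * min_sp * min(shape.channels, config.fixed_width),
                 config.fixed_width)
    lower = vc_dimension(
        w + dense_weight_count(min_in, config.n_classes), l + 1, config.log_base
    )
    return lower <= config.max_vc


def iter_structures(config: EnumerationConfig) -> Iterator[NetworkStructure]:
    """Lazily yield every admissible structure in canonical tree order.

    With ``emission='every_node'`` each admissible prefix (including the
    empty one) yields the structure "prefix + output layer"; with
    ``'leaf_only'`` only prefixes with no admissible extension do.
    """
    out = config.output_layer

    def emit(prefix: tuple[LayerSpec, ...]) -> NetworkStructure:
        return NetworkStructure(prefix + (out,), config.input_shape, config.log_base)

    def walk(prefix, shape, w, l) -> Iterator[NetworkStructure]:
        if len(prefix) > config.max_depth:
            raise RecursionError(
                f"enumeration exceeded max_depth={config.max_depth}; "
                "raise EnumerationConfig.max_depth if this space is intended"
            )
        admissible = _admissible(config, shape, w, l)
        if admissible and config.emission == "every_node":
            yield emit(prefix)
        any_admissible_child = False
        for layer in _children(config, shape):
            cs, cw, cl = _child_state(shape, w, l, layer)
            if _explorable(config, cs, cw, cl):
                any_admissible_child = (
                    any_admissible_child or _admissible(config, cs, cw, cl)
                )
                yield from walk(prefix + (layer,), cs, cw, cl)
        if (
            config.emission == "leaf_only"
            and admissible
            and not any_admissible_child
        ):
            yield emit(prefix)

    if _explorable(config, config.input_shape, 0, 0):
        yield from walk((), config.input_shape, 0, 0)


def enumerate_structures(config: EnumerationConfig) -> list[NetworkStructure]:
    """All admissible structures, sorted by canonical encoding, no duplicates."""
    structures = sorted(iter_structures(config), key=lambda s: s.encoding)
    return structures


def count_structures(config: EnumerationConfig) -> int:
    """Exact structure count, without materializing the space.

    Uses dynamic programming over collapsed prefix states (spatial extent,
    channels/units, weight and layer totals): two prefixes with the same
    state root identical subtrees, so large spaces collapse to a few
    thousand distinct states.  Agrees with ``len(enumerate_structures(c))``
    (property-tested against a brute-force oracle on small spaces).
    """
    memo: dict[tuple, tuple[int, int]] = {}
    limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(limit, 100_000))
    try:

        def sub(shape: TensorShape, w: int, l: int) -> tuple[int, int]:
            """(emitted-structure counts) for the subtree rooted at this
            state, inclusive: (every-node count, leaf-only count)."""
            key = (shape, w, l)
            hit = memo.get(key)
            if hit is not None:
                return hit
            admissible = _admissible(config, shape, w, l)
            every = 1 if admissible else 0
            leaf = 0
            any_admissible_child = False
            for layer in _children(config, shape):
                cs, cw, cl = _child_state(shape, w, l, layer)
                if _explorable(config, cs, cw, cl):
                    any_admissible_child = (
                        any_admissible_child or _admissible(config, cs, cw, cl)
                    )
                    ce, clf = sub(cs, cw, cl)
                    every += ce
                    leaf += clf
            if admissible and not any_admissible_child:
                leaf += 1
            memo[key] = (every, leaf)
            return every, leaf

        if not _explorable(config, config.input_shape, 0, 0):
            return 0
        every, leaf = sub(config.input_shape, 0, 0)
        return every if config.emission == "every_node" else leaf
    finally:
        sys.setrecursionlimit(limit)


def permute_widths(
    structure: NetworkStructure, width_options: Iterable[int]
) -> list[NetworkStructure]:
    """All assignments of ``width_options`` to the width-bearing layers.

    Width-bearing layers are the conv layers and the hidden dense layers;
    the output width stays equal to the class count and pooling windows and
    kernel sizes are untouched.  The result has exactly
    ``len(options) ** (n_conv + n_dense)`` structures.
    """
    options = sorted(set(width_options))
    if not options:
        raise ValueError("width_options must be non-empty")
    slots = [i for i, l in enumerate(structure.layers) if l.kind in (CONV, DENSE)]
    result = []
    for combo in itertools.product(options, repeat=len(slots)):
        layers = list(structure.layers)
        for idx, width in zip(slots, combo):
            layers[idx] = replace(layers[idx], width=width)
        result.append(
            NetworkStructure(tuple(layers), structure.input_shape, structure.log_base)
        )
    return result


_KIND_TO_TOKEN = {CONV: "Conv", MAXPOOL: "MP", DENSE: "Full", OUTPUT: "Full"}


def encode_structure(structure: NetworkStructure, include_widths: bool = False) -> str:
    """Canonical structure string, e.g. ``"Conv5 → MP2 → Full → Full"``.

    With ``include_widths=True`` width-bearing layers carry a ``,width``
    suffix and the output layer shows the class count
    (``"Conv5,32 → MP2 → Full,10"`` style), which makes width permutations
    distinguishable.
    """
    parts = []
    for layer in structure.layers:
        token = _KIND_TO_TOKEN[layer.kind]
        if layer.kind in (CONV, MAXPOOL):
            token += str(layer.size)
        if include_widths and layer.width is not None:
            token += f",{layer.width}"
        parts.append(token)
    return " → ".join(parts)


def decode_structure(text: str, config: EnumerationConfig) -> NetworkStructure:
    """Parse a structure string back into a :class:`NetworkStructure`.

    Accepts the Table-style grammar ``Layer(,width)? (→ Layer(,width)?)*``
    with ``Layer ∈ {ConvK, MPK, Full}`` and either ``→`` or ``->`` as the
    separator.  Missing widths default to ``config.fixed_width``; the final
    ``Full`` is the output layer and defaults to ``config.n_classes`` units.
    A width given on an MP token (Table-2 style) is accepted and ignored.
    """
    tokens = [t.strip() for t in text.replace("->", "→").split("→")]
    if tokens == [""]:
        raise StructureParseError("empty structure string", 0)
    layers: list[LayerSpec] = []
    for pos, token in enumerate(tokens):
        if not token:
            raise StructureParseError("empty layer token", pos)
        name, _, width_txt = token.partition(",")
        name = name.strip()
        width = None
        if width_txt.strip():
            try:
                width = int(width_txt)
            except ValueError:
                raise StructureParseError(f"bad width {width_txt!r}", pos) from None
        terminal = pos == len(tokens) - 1
        try:
            if name.startswith("Conv"):
                layers.append(
                    LayerSpec(CONV, size=int(name[4:]), width=width or config.fixed_width)
                )
            elif name.startswith("MP"):
                layers.append(LayerSpec(MAXPOOL, size=int(name[2:])))
            elif name == "Full":
                if terminal:
                    layers.append(LayerSpec(OUTPUT, width=width or config.n_classes))
                else:
                    layers.append(LayerSpec(DENSE, width=width or config.fixed_width))
            else:
                raise StructureParseError(f"unknown layer token {name!r}", pos)
        except ValueError as exc:
            if isinstance(exc, StructureParseError):
                raise
            raise StructureParseError(f"malformed layer token {token!r}", pos) from None
    if layers[-1].kind == OUTPUT and layers[-1].width != config.n_classes:
        raise StructureParseError(
            f"output width {layers[-1].width} != n_classes {config.n_classes}",
            len(tokens) - 1,
        )
    return NetworkStructure(tuple(layers), config.input_shape, config.log_base)


def structure_record(structure: NetworkStructure) -> dict:
    """JSON-serializable summary used in the JSONL structure lists."""
    return {
        "encoding": encode_structure(structure, include_widths=True),
        "total_weights": structure.total_weights,
        "L": structure.weighted_layer_count,
        "vc_dimension": structure.vc_dimension,
        "depth": structure.depth,
        "n_conv": structure.n_conv,
        "n_dense": structure.n_dense,
        "n_maxpool": structure.n_maxpool,
    }


def write_structures_jsonl(structures: Iterable[NetworkStructure], path) -> None:
    with open(path, "w") as fh:
        for s in structures:
            fh.write(json.dumps(structure_record(s)) + "\n")


def read_structures_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def calibration_sweep(
    cases: Sequence[tuple[EnumerationConfig, int]],
    log_bases: Sequence[float] = (2.0, math.e, 10.0),
    emissions: Sequence[str] = ("every_node", "leaf_only"),
) -> list[dict]:
    """Count the structure space under each (log base, emission rule) pair.

    ``cases`` pairs an :class:`EnumerationConfig` with a reference count.
    Returns one record per configuration with the per-case counts and
    whether all reference counts were matched exactly.  This documents which
    concretization of the asymptotic capacity bound a given reference count
    corresponds to, if any.
    """
    base_names = {2.0: "log2", math.e: "ln", 10.0: "log10"}
    records = []
    for base in log_bases:
        for emission in emissions:
            counts = [
                count_structures(replace(cfg, log_base=base, emission=emission))
                for cfg, _ in cases
            ]
            records.append(
                {
                    "log_base": base_names.get(base, str(base)),
                    "emission": emission,
                    "counts": counts,
                    "reference": [ref for _, ref in cases],
                    "matches": all(c == r for c, (_, r) in zip(counts, cases)),
                }
            )
    return records
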