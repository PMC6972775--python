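"""Structure-space unit and property tests: weight accounting, the
capacity bound, shape propagation, enumeration and the string encoding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vcnas import (
    EnumerationConfig,
    GeometryError,
    NetworkStructure,
    StructureParseError,
    TensorShape,
    TopologyError,
    conv_weight_count,
    decode_structure,
    dense_weight_count,
    encode_structure,
    enumerate_structures,
    permute_widths,
    propagate_shape,
    structure_vc,
    vc_dimension,
)
from vcnas.arch_space import (
    CONV,
    DENSE,
    MAXPOOL,
    LayerSpec,
    count_structures,
    _accounting,
)

from conftest import brute_force_structures


class TestWeightCounts:
    @pytest.mark.parametrize(
        "k,cin,cout,expected",
        [(5, 1, 10, 260), (7, 3, 10, 1480), (1, 1, 1, 2)],
    )
    def test_conv(self, k, cin, cout, expected):
        assert conv_weight_count(k, cin, cout) == expected

    @pytest.mark.parametrize(
        "din,dout,expected",
        [(784, 10, 7850), (1, 1, 2), (7840, 10, 78410)],
    )
    def test_dense(self, din, dout, expected):
        assert dense_weight_count(din, dout) == expected

    @pytest.mark.parametrize("bad", [(0, 1, 1), (5, 0, 1), (5, 1, -1)])
    def test_conv_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            conv_weight_count(*bad)

    def test_dense_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dense_weight_count(0, 10)


class TestShapePropagation:
    def test_conv_preserves_extent(self):
        out = propagate_shape(TensorShape(28, 28, 1), LayerSpec(CONV, size=5, width=10))
        assert (out.height, out.width, out.channels) == (28, 28, 10)

    def test_pool_ceil_division(self):
        out = propagate_shape(TensorShape(28, 28, 10), LayerSpec(MAXPOOL, size=4))
        assert (out.height, out.channels) == (7, 10)
        assert propagate_shape(TensorShape(7, 7, 10), LayerSpec(MAXPOOL, size=2)).height == 4

    def test_dense_flattens(self):
        shape = TensorShape(7, 7, 10)
        assert shape.flat_dim == 490
        out = propagate_shape(shape, LayerSpec(DENSE, width=10))
        assert out.flattened and out.flat_dim == 10

    def test_conv_after_flatten_is_topology_error(self):
        flat = propagate_shape(TensorShape(8, 8, 1), LayerSpec(DENSE, width=4))
        with pytest.raises(TopologyError):
            propagate_shape(flat, LayerSpec(CONV, size=3, width=4))

    def test_oversized_pool_is_geometry_error(self):
        with pytest.raises(GeometryError):
            propagate_shape(TensorShape(3, 3, 1), LayerSpec(MAXPOOL, size=4))


class TestVCDimension:
    def test_single_dense_layer_value(self):
        # 7850 * log2(7850) computed independently at high precision
        assert vc_dimension(7850, 1) == pytest.approx(1.0157e5, rel=1e-4)

    def test_smallest_case(self):
        assert vc_dimension(2, 1) == 2.0

    def test_zero_weights_convention(self):
        assert vc_dimension(0, 1) == 0.0

    @given(
        w=st.integers(min_value=2, max_value=10**7),
        l=st.integers(min_value=1, max_value=40),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_layers_and_weights(self, w, l):
        assert vc_dimension(w, l + 1) > vc_dimension(w, l)
        assert vc_dimension(w + 1, l) > vc_dimension(w, l)


class TestStructureVC:
    def test_empty_prefix_is_bare_output(self, mnist_like_config):
        assert structure_vc((), mnist_like_config) == vc_dimension(7850, 1)

    def test_conv_prefix(self, mnist_like_config):
        prefix = (LayerSpec(CONV, size=5, width=10),)
        expected = vc_dimension(260 + 78410, 2)
        assert structure_vc(prefix, mnist_like_config) == pytest.approx(expected)

    def test_pool_prefix_shrinks_output_layer(self, mnist_like_config):
        prefix = (LayerSpec(MAXPOOL, size=2),)
        # pooling adds no weights but the output layer now reads 14*14*1=196
        assert structure_vc(prefix, mnist_like_config) == pytest.approx(
            vc_dimension(196 * 10 + 10, 1)
        )

    def test_invalid_prefix_raises(self, mnist_like_config):
        prefix = (LayerSpec(DENSE, width=10), LayerSpec(CONV, size=5, width=10))
        with pytest.raises(TopologyError):
            structure_vc(prefix, mnist_like_config)


class TestEnumeration:
    def test_minimal_cap_gives_single_structure(self):
        # without pooling every extension adds weights, so a cap just above
        # the bare output layer admits exactly that one structure
        shape = TensorShape(8, 8, 1)
        base = structure_vc((), EnumerationConfig(shape, 2, 1.0, (3,), (), 2))
        config = EnumerationConfig(shape, 2, base * 1.01, (3,), (), 2)
        structures = enumerate_structures(config)
        assert [s.encoding for s in structures] == ["Full"]

    def test_cap_below_minimal_is_empty(self):
        shape = TensorShape(8, 8, 1)
        config = EnumerationConfig(shape, 2, 10.0, (3,), (), 2)
        assert enumerate_structures(config) == []
        assert count_structures(config) == 0

    def test_pooling_can_undercut_the_bare_output_layer(self):
        # pooled prefixes shrink the output layer, so with pools in the
        # alphabet the space need not be empty below the bare-output VC
        shape = TensorShape(8, 8, 1)
        bare = structure_vc((), EnumerationConfig(shape, 2, 1.0, (3,), (2,), 2))
        config = EnumerationConfig(shape, 2, bare * 0.5, (3,), (2,), 2)
        structures = enumerate_structures(config)
        assert structures and all(s.n_maxpool >= 1 for s in structures)
        assert all(s.vc_dimension <= config.max_vc for s in structures)

    def test_sorted_unique_and_admissible(self, tiny_config):
        structures = enumerate_structures(tiny_config)
        encodings = [s.encoding for s in structures]
        assert encodings == sorted(encodings)
        assert len(set(encodings)) == len(encodings)
        for s in structures:
            assert s.vc_dimension <= tiny_config.max_vc
            assert s.layers[-1].width == tiny_config.n_classes

    def test_count_matches_materialized(self, tiny_config):
        assert count_structures(tiny_config) == len(enumerate_structures(tiny_config))

    def test_leaf_only_is_subset_of_every_node(self, tiny_config):
        from dataclasses import replace

        leaves = {s.encoding for s in enumerate_structures(replace(tiny_config, emission="leaf_only"))}
        every = {s.encoding for s in enumerate_structures(tiny_config)}
        assert leaves and leaves <= every

    def test_matches_brute_force_oracle(self, tiny_config):
        got = {s.encoding for s in enumerate_structures(tiny_config)}
        assert got == brute_force_structures(tiny_config, max_len=14)

    def test_monotone_in_cap_and_width(self, tiny_config):
        from dataclasses import replace

        base = count_structures(tiny_config)
        assert count_structures(replace(tiny_config, max_vc=tiny_config.max_vc * 2)) >= base
        assert count_structures(replace(tiny_config, fixed_width=4)) <= base

    def test_weight_accounting_recomputes(self, tiny_config):
        for s in enumerate_structures(tiny_config)[::17]:
            w, l, _ = _accounting(s.layers, s.input_shape)
            assert (w, l) == (s.total_weights, s.weighted_layer_count)
            assert s.vc_dimension == pytest.approx(vc_dimension(w, l))


class TestPermuteWidths:
    def test_counting_law_small(self, tiny_config):
        s = decode_structure("Conv3 → Conv3 → MP2 → Full → Full", tiny_config)
        perms = permute_widths(s, [32, 64])
        assert len(perms) == 2 ** (2 + 1)
        assert len({encode_structure(p, include_widths=True) for p in perms}) == 8

    def test_reference_topology_count(self):
        # 4 conv + 3 hidden dense layers over three width options
        config = EnumerationConfig(TensorShape(28, 28, 1), 10, 3_500_000)
        s = decode_structure(
            "Conv5 → MP2 → Conv5 → MP2 → Conv5 → Conv7 → Full → Full → Full → Full",
            config,
        )
        assert len(permute_widths(s, [32, 64, 128])) == 3**7

    def test_single_option_replaces_all(self, tiny_config):
        s = decode_structure("Conv3 → Full → Full", tiny_config)
        (only,) = permute_widths(s, [5])
        widths = [l.width for l in only.layers]
        assert widths == [5, 5, tiny_config.n_classes]

    def test_topology_is_preserved(self, tiny_config):
        s = decode_structure("Conv3 → MP2 → Full → Full", tiny_config)
        for p in permute_widths(s, [4, 8]):
            assert [l.kind for l in p.layers] == [l.kind for l in s.layers]
            assert [l.size for l in p.layers] == [l.size for l in s.layers]


class TestEncoding:
    def test_reference_row_round_trips(self):
        config = EnumerationConfig(TensorShape(32, 32, 3), 10, 3_500_000)
        text = "Conv5 → MP4 → Full → Full → Full"
        s = decode_structure(text, config)
        assert len(s.layers) == 5 and s.n_conv == 1 and s.n_dense == 2
        assert encode_structure(s) == text

    def test_output_only(self, tiny_config):
        s = decode_structure("Full", tiny_config)
        assert s.depth == 0 and s.total_weights == dense_weight_count(64, 2)

    def test_width_suffixes(self, tiny_config):
        s = decode_structure("Conv3,8 → MP2 → Full,4 → Full", tiny_config)
        assert [l.width for l in s.layers] == [8, None, 4, 2]
        assert encode_structure(s, include_widths=True) == "Conv3,8 → MP2 → Full,4 → Full,2"

    def test_ascii_arrow_accepted(self, tiny_config):
        assert decode_structure("Conv3 -> Full", tiny_config).n_conv == 1

    @pytest.mark.parametrize("bad", ["", "Conv", "Blah3", "Conv3,, → Full", "Conv3 → → Full"])
    def test_parse_errors_carry_position(self, bad, tiny_config):
        with pytest.raises(StructureParseError):
            decode_structure(bad, tiny_config)

    def test_round_trip_over_enumerated_structures(self, tiny_config):
        structures = enumerate_structures(tiny_config)
        rng = np.random.default_rng(5)
        for s in rng.choice(len(structures), size=100, replace=True):
            structure = structures[s]
            again = decode_structure(structure.encoding, tiny_config)
            assert again == structure
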