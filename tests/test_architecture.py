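"""Architecture construction, parameter counting, MACs, factorization."""

import numpy as np
import pytest

from msrn.architecture import (
    BLOCK_CHANNELS,
    VARIANT_LAYER_COUNTS,
    LayerSpec,
    MultiScaleConfig,
    build_ms_srn,
    build_srn,
    conv_stack_macs,
    count_macs,
    count_parameters,
    count_reference_resnet,
    layer_macs,
    srn_config,
    substitute_kernels,
)
from msrn.nn import MaxPool2x2


def oracle_srn_params(layer_counts, channels=BLOCK_CHANNELS, in_channels=3,
                      num_classes=4, residual=True):
    """Closed-form per-layer summation, independent of the network builder."""
    total = 0
    c = in_channels
    for b, (n_layers, out) in enumerate(zip(layer_counts, channels)):
        k = 7 if b == 0 else 3
        for _ in range(n_layers):
            total += k * k * c * out + out
            c = out
    if residual:
        cin = channels[0]
        for out in channels[1:]:
            if cin != out:  # 1x1 projection with bias at channel transitions
                total += cin * out + out
            cin = out
    total += channels[-1] * num_classes + num_classes
    return total


EXPECTED_COUNTS = {
    ("8-layer", True): 1_804_932,
    ("10-layer", True): 1_961_764,
    ("12-layer", True): 2_588_772,
    ("12-layer", False): 2_413_732,
}


@pytest.mark.parametrize("variant,residual", list(EXPECTED_COUNTS))
def test_srn_parameter_counts_match_closed_form(variant, residual):
    expected = oracle_srn_params(VARIANT_LAYER_COUNTS[variant], residual=residual)
    assert expected == EXPECTED_COUNTS[(variant, residual)]
    net = build_srn(srn_config(variant, residual=residual))
    assert count_parameters(net).parameter_count == expected


@pytest.mark.parametrize("variant,millions", [
    ("8-layer", 1.80), ("10-layer", 1.96), ("12-layer", 2.59),
])
def test_srn_counts_round_to_printed_millions(variant, millions):
    net = build_srn(srn_config(variant))
    assert count_parameters(net).parameter_count_millions == millions


def test_plain_vs_residual_difference_is_exactly_the_projections():
    res = count_parameters(build_srn(srn_config("12-layer"))).parameter_count
    plain = count_parameters(
        build_srn(srn_config("12-layer", residual=False))).parameter_count
    weights = 32 * 64 + 64 * 128 + 128 * 256 + 256 * 512
    biases = 64 + 128 + 256 + 512
    assert weights == 174_080 and biases == 960
    assert res - plain == weights + biases


def test_ms_srn_parameter_count():
    ms = build_ms_srn(MultiScaleConfig(branch_sizes=(448, 224)))
    summary = count_parameters(ms)
    assert summary.parameter_count == 5_177_540
    assert summary.parameter_count_millions == 5.18


def test_single_branch_ms_equals_standalone_srn():
    ms = build_ms_srn(MultiScaleConfig(branch_sizes=(224,)))
    srn = build_srn(srn_config("12-layer"))
    assert count_parameters(ms).parameter_count == \
        count_parameters(srn).parameter_count


def test_three_branch_count_matches_closed_form():
    ms = build_ms_srn(MultiScaleConfig(branch_sizes=(112, 224, 448)))
    trunk = oracle_srn_params(VARIANT_LAYER_COUNTS["12-layer"]) - (512 * 4 + 4)
    assert count_parameters(ms).parameter_count == 3 * trunk + (3 * 512 * 4 + 4)


def test_unknown_variant_rejected():
    with pytest.raises(ValueError, match="unknown variant"):
        srn_config("14-layer")


def test_invalid_input_side_rejected():
    net = build_srn(srn_config("8-layer"))
    with pytest.raises(ValueError, match="side"):
        net.forward(np.zeros((1, 3, 50, 50), dtype=np.float32))


@pytest.mark.parametrize("side", [64, 128])
def test_forward_shape_contract(side):
    """Block sides halve six times; pooled feature is 512-d regardless of side."""
    net = build_srn(srn_config("8-layer"), seed=0)
    x = np.random.default_rng(0).random((2, 3, side, side), dtype=np.float32)
    h = x
    expected = side
    for block in net.blocks:
        h = block.forward(h)
        expected //= 2
        assert h.shape[-2:] == (expected, expected)
    feats = net.features(x)
    logits = net.forward(x)
    assert feats.shape == (2, 512)
    assert logits.shape == (2, 4)


def test_build_and_forward_are_deterministic():
    x = np.random.default_rng(1).random((2, 3, 64, 64), dtype=np.float32)
    a = build_srn(srn_config("10-layer"), seed=42)
    b = build_srn(srn_config("10-layer"), seed=42)
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa.value, pb.value)
    assert np.array_equal(a.forward(x), b.forward(x))
    c = build_srn(srn_config("10-layer"), seed=43)
    assert not np.array_equal(c.forward(x), a.forward(x))


def test_residual_block_passthrough_when_main_path_zeroed():
    """Zeroed main path in an identity-skip block reduces to pooled input."""
    net = build_srn(srn_config("8-layer"), seed=0)
    block = net.blocks[1]  # 32 -> 32: identity skip
    for conv in block.convs:
        conv.weight.value[...] = 0
        conv.bias.value[...] = 0
    x = np.abs(np.random.default_rng(2).random((2, 32, 32, 32))).astype(np.float32)
    out = block.forward(x)
    pool = MaxPool2x2()
    assert np.allclose(out, pool.forward(x), atol=1e-6)


def test_projected_skip_block_reduces_to_projection():
    net = build_srn(srn_config("8-layer"), seed=0)
    block = net.blocks[2]  # 32 -> 64: 1x1 projection skip
    for conv in block.convs:
        conv.weight.value[...] = 0
        conv.bias.value[...] = 0
    x = np.abs(np.random.default_rng(3).random((1, 32, 16, 16))).astype(np.float32)
    proj = block.proj.forward(x)
    expected = MaxPool2x2().forward(np.maximum(proj, 0))
    assert np.allclose(block.forward(x), expected, atol=1e-6)


# ---------------------------------------------------------------------------
# MAC counting
# ---------------------------------------------------------------------------

def test_single_conv_macs_closed_form():
    assert layer_macs(3, 32, 32, 112) == 9216 * 12544 == 115_605_504


def test_factorization_cost_ratios():
    r1 = conv_stack_macs([5], 16) / conv_stack_macs([3], 16)
    r2 = conv_stack_macs([5], 16) / conv_stack_macs([3, 3], 16)
    assert round(r1, 2) == 2.78
    assert round(r2, 2) == 1.39


def test_count_macs_additive_and_quadratic_in_side():
    net = build_srn(srn_config("8-layer"))
    m64, m128 = count_macs(net, 64), count_macs(net, 128)
    head = 512 * 4
    # conv part scales exactly 4x when the side doubles; the head does not
    assert m128 - head == 4 * (m64 - head)
    # additivity: total equals the per-layer closed-form sum
    total = 0
    side, c = 64, 3
    for spec in net.config.blocks:
        for layer in spec.layers:
            total += layer_macs(layer.kernel_size, c, layer.out_channels, side)
            c = layer.out_channels
        side //= 2
    side, cin = 64, 3
    for spec in net.config.blocks:
        if spec.residual and cin != spec.out_channels:
            total += layer_macs(1, cin, spec.out_channels, side)
        cin = spec.out_channels
        side //= 2
    assert m64 == total + head


# ---------------------------------------------------------------------------
# Kernel substitution
# ---------------------------------------------------------------------------

def test_substitution_identity_rule_is_noop():
    cfg = srn_config("12-layer")
    assert substitute_kernels(cfg, {}) == cfg


def test_substitution_five_to_two_threes_parameter_factor():
    cfg = srn_config("8-layer")
    # swap one homogeneous 3x3 pair for a 5x5, then compare parameters
    merged = substitute_kernels(cfg, {5: (3, 3)}, inverse=True)
    n_merged = sum(len(b.layers) for b in merged.blocks)
    assert n_merged < cfg.conv_layer_count
    p_fact = count_parameters(build_srn(cfg)).parameter_count
    p_merged = count_parameters(build_srn(merged)).parameter_count
    # per substituted 32-channel pair: factored 18*c^2+2c vs merged 25*c^2+c
    c = 32
    n_subs = cfg.conv_layer_count - n_merged
    assert n_subs == 1  # only block 2 has a homogeneous 3x3 pair in SRN-8
    assert p_merged - p_fact == (25 * c * c + c) - (18 * c * c + 2 * c)


def test_substitution_round_trip_restores_layer_counts():
    cfg = srn_config("8-layer")
    merged = substitute_kernels(cfg, {5: (3, 3)}, inverse=True)
    restored = substitute_kernels(merged, {5: (3, 3)})
    assert [len(b.layers) for b in restored.blocks] == \
        [len(b.layers) for b in cfg.blocks]
    assert [[l.kernel_size for l in b.layers] for b in restored.blocks] == \
        [[l.kernel_size for l in b.layers] for b in cfg.blocks]


def test_substitution_rejects_receptive_field_mismatch():
    with pytest.raises(ValueError, match="receptive field"):
        substitute_kernels(srn_config("8-layer"), {7: (3, 3)})


# ---------------------------------------------------------------------------
# Reference residual networks
# ---------------------------------------------------------------------------

def test_resnet18_canonical_1000_class_count():
    assert count_reference_resnet(18, 1000).parameter_count == 11_689_512


def test_resnet18_four_class_rounds_to_printed_value():
    assert count_reference_resnet(18, 4).parameter_count_millions == 11.18


def test_resnet101_canonical_1000_class_count():
    assert count_reference_resnet(101, 1000).parameter_count == 44_549_160


def test_srn12_to_resnet101_parameter_ratio():
    srn12 = count_parameters(build_srn(srn_config("12-layer"))).parameter_count
    r101 = count_reference_resnet(101, 4).parameter_count
    assert round(100 * srn12 / r101, 1) == 6.1


def test_unsupported_reference_depth_rejected():
    with pytest.raises(ValueError, match="depth"):
        count_reference_resnet(34)


def test_layer_spec_invariants():
    with pytest.raises(ValueError):
        LayerSpec(kernel_size=4, out_channels=8)
    with pytest.raises(ValueError):
        LayerSpec(kernel_size=3, out_channels=0)
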