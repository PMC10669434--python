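"""SRN and MS-SRN architectures for retinal OCT B-scan classification.

The sparse residual network (SRN) is a lightweight CNN of six convolutional
blocks.  The stem block is a single 7x7 convolution; every other layer is a
3x3 convolution (large kernels are factorized into stacks of 3x3 layers,
which preserves the receptive field at a lower parameter cost).  Each block
ends with a 2x2 stride-2 max-pool, so an input of side ``s`` (divisible by
64) shrinks to ``s/64`` before global average pooling to a 512-vector.  With
residual learning on, each block adds a skip from its input to its last
convolution's output — identity when the channel count is unchanged, a 1x1
projection convolution (with bias) at the four channel transitions.

The multi-scale model (MS-SRN) runs one independent SRN trunk per input
scale (default 448 local + 224 global), concatenates the pooled 512-vectors
and applies a single fully connected head over the fused feature.

Three depth variants are defined by their per-block 3x3 layer counts:

==========  =====================  ==========
variant     layers per block       parameters
==========  =====================  ==========
8-layer     1, 2, 2, 1, 1, 1       1.80 M
10-layer    1, 3, 2, 2, 1, 1       1.96 M
12-layer    1, 3, 3, 2, 2, 1       2.59 M
==========  =====================  ==========

No normalization layers are used; every convolution (projections included)
and the classifier carry a bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn

VARIANT_LAYER_COUNTS = {
    "8-layer": (1, 2, 2, 1, 1, 1),
    "10-layer": (1, 3, 2, 2, 1, 1),
    "12-layer": (1, 3, 3, 2, 2, 1),
}
BLOCK_CHANNELS = (32, 32, 64, 128, 256, 512)
FEATURE_DIM = 512
VALID_KERNELS = (1, 3, 5, 7)


@dataclass(frozen=True)
class LayerSpec:
    """One convolutional layer: square kernel, output channels, stride."""

    kernel_size: int
    out_channels: int
    stride: int = 1
    has_bias: bool = True

    def __post_init__(self) -> None:
        if self.kernel_size not in VALID_KERNELS:
            raise ValueError(f"kernel_size must be one of {VALID_KERNELS}, got {self.kernel_size}")
        if self.out_channels <= 0:
            raise ValueError("out_channels must be positive")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class BlockSpec:
    """An ordered stack of conv layers, optionally residual, ending in a pool."""

    layers: tuple[LayerSpec, ...]
    residual: bool = False
    followed_by_pool: bool = True

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("a block needs at least one layer")

    @property
    def out_channels(self) -> int:
        return self.layers[-1].out_channels


@dataclass(frozen=True)
class SRNConfig:
    """Full architectural genotype of one SRN variant."""

    variant_name: str
    blocks: tuple[BlockSpec, ...]
    in_channels: int = 3
    feature_dim: int = FEATURE_DIM
    num_classes: int = 4
    residual: bool = True
    normalization: bool = False

    def __post_init__(self) -> None:
        if len(self.blocks) != 6:
            raise ValueError("an SRN has exactly six convolutional blocks")
        if self.normalization:
            raise NotImplementedError("normalization layers are defined but not implemented")

    @property
    def conv_layer_count(self) -> int:
        return sum(len(b.layers) for b in self.blocks)


@dataclass(frozen=True)
class MultiScaleConfig:
    """Multi-branch configuration: one independent SRN trunk per input scale."""

    branch_sizes: tuple[int, ...] = (448, 224)
    branch_config: SRNConfig | None = None
    num_classes: int = 4

    def __post_init__(self) -> None:
        if len(self.branch_sizes) == 0:
            raise ValueError("at least one branch size is required")
        for s in self.branch_sizes:
            _check_side(s)
        if self.branch_config is None:
            object.__setattr__(self, "branch_config", srn_config("12-layer"))

    @property
    def fused_dim(self) -> int:
        return self.branch_config.feature_dim * len(self.branch_sizes)


@dataclass(frozen=True)
class ModelSummary:
    parameter_count: int
    mac_count: int | None = None

    def __post_init__(self) -> None:
        if self.parameter_count <= 0:
            raise ValueError("parameter_count must be positive")

    @property
    def parameter_count_millions(self) -> float:
        return round(self.parameter_count / 1e6, 2)


def _check_side(side: int) -> None:
    # floor-mode pooling makes any even side >= 64 well defined (224 -> 3x3
    # after six pools, as in the canonical variants)
    if side < 64 or side % 2 != 0:
        raise ValueError(f"input side must be an even integer >= 64, got {side}")


def srn_config(variant_name: str, *, in_channels: int = 3, num_classes: int = 4,
               residual: bool = True) -> SRNConfig:
    """Construct the canonical block plan of an SRN depth variant."""
    if variant_name not in VARIANT_LAYER_COUNTS:
        raise ValueError(
            f"unknown variant {variant_name!r}; expected one of {sorted(VARIANT_LAYER_COUNTS)}")
    counts = VARIANT_LAYER_COUNTS[variant_name]
    blocks = []
    for b, (n_layers, channels) in enumerate(zip(counts, BLOCK_CHANNELS)):
        if b == 0:
            layers = (LayerSpec(kernel_size=7, out_channels=channels),)
            block_residual = False  # no skip across the stem
        else:
            layers = tuple(LayerSpec(kernel_size=3, out_channels=channels)
                           for _ in range(n_layers))
            block_residual = residual
        blocks.append(BlockSpec(layers=layers, residual=block_residual))
    return SRNConfig(variant_name=variant_name, blocks=tuple(blocks),
                     in_channels=in_channels, num_classes=num_classes, residual=residual)


class ConvBlock:
    """Conv stack + optional residual skip + ReLU + 2x2 max-pool.

    Every convolution is followed by a ReLU; in a residual block the skip
    (identity, or 1x1 projection when channels change) is added to the last
    convolution's output *before* that final ReLU, and pooling comes last.
    The pre-pool activation is retained for Grad-CAM when capture is on.
    """

    def __init__(self, spec: BlockSpec, in_channels: int, rng: np.random.Generator,
                 name: str) -> None:
        self.spec = spec
        self.in_channels = in_channels
        self.convs: list[nn.Conv2d] = []
        c = in_channels
        for i, layer in enumerate(spec.layers):
            self.convs.append(nn.Conv2d(c, layer.out_channels, layer.kernel_size,
                                        bias=layer.has_bias, rng=rng, name=f"{name}.conv{i}"))
            c = layer.out_channels
        if spec.residual:
            # start each residual branch at zero so a block is initially the
            # (projected) identity; keeps activation scale flat with depth in
            # the absence of normalization layers and speeds early training
            self.convs[-1].weight.value[...] = 0.0
        self.relus = [nn.ReLU() for _ in spec.layers]
        self.proj: nn.Conv2d | None = None
        if spec.residual and in_channels != spec.out_channels:
            self.proj = nn.Conv2d(in_channels, spec.out_channels, 1, bias=True,
                                  rng=rng, name=f"{name}.proj")
        self.pool = nn.MaxPool2x2() if spec.followed_by_pool else None
        # Grad-CAM capture slots (pre-pool, post-activation map)
        self.capture = False
        self.activation: np.ndarray | None = None
        self.activation_grad: np.ndarray | None = None
        self._skip_in: np.ndarray | None = None

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for conv in self.convs:
            ps.extend(conv.params())
        if self.proj is not None:
            ps.extend(self.proj.params())
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for conv, relu in zip(self.convs[:-1], self.relus[:-1]):
            h = relu.forward(conv.forward(h, train), train)
        h = self.convs[-1].forward(h, train)
        if self.spec.residual:
            skip = self.proj.forward(x, train) if self.proj is not None else x
            h = h + skip
        h = self.relus[-1].forward(h, train)
        if self.capture:
            self.activation = h
        if self.pool is not None:
            h = self.pool.forward(h, train)
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.pool is not None:
            dy = self.pool.backward(dy)
        dy = self.relus[-1].backward(dy)
        if self.capture:
            self.activation_grad = dy
        if self.spec.residual:
            dskip = self.proj.backward(dy) if self.proj is not None else dy
        else:
            dskip = 0.0
        dx = self.convs[-1].backward(dy)
        for conv, relu in zip(reversed(self.convs[:-1]), reversed(self.relus[:-1])):
            dx = conv.backward(relu.backward(dx))
        if dx is None:  # first layer of the network opted out of input grads
            return None
        return dx + dskip

    def pre_pool_output(self, x: np.ndarray) -> np.ndarray:
        """Forward through the block but stop before the max-pool."""
        self.capture, old = True, self.capture
        try:
            self.forward(x)
            return self.activation
        finally:
            self.capture = old


class SRN:
    """Single-scale sparse residual network: 6 blocks -> GAP -> C-way head."""

    def __init__(self, config: SRNConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self.blocks: list[ConvBlock] = []
        c = config.in_channels
        for b, spec in enumerate(config.blocks):
            block = ConvBlock(spec, c, rng, name=f"block{b + 1}")
            self.blocks.append(block)
            c = spec.out_channels
        if c != config.feature_dim:
            raise ValueError("last block channels must equal feature_dim")
        self.blocks[0].convs[0].needs_input_grad = False
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Linear(config.feature_dim, config.num_classes, rng=rng, name="head")

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for b in self.blocks:
            ps.extend(b.params())
        ps.extend(self.head.params())
        return ps

    def trunk_params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for b in self.blocks:
            ps.extend(b.params())
        return ps

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        _check_side(x.shape[-1])
        if x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels}-channel input")
        h = x.astype(nn.DTYPE, copy=False)
        for b in self.blocks:
            h = b.forward(h, train)
        return self.gap.forward(h, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits of shape (N, C)."""
        return self.head.forward(self.features(x, train), train)

    __call__ = forward

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        d = self.gap.backward(d)
        for b in reversed(self.blocks):
            d = b.backward(d)
        return d


class MSSRN:
    """Multi-scale model: independent SRN trunks fused by one linear head."""

    def __init__(self, config: MultiScaleConfig, seed: int = 0) -> None:
        self.config = config
        self.branches: list[SRN] = []
        ss = np.random.SeedSequence(seed)
        child_seeds = ss.generate_state(len(config.branch_sizes) + 1)
        for i, _ in enumerate(config.branch_sizes):
            self.branches.append(SRN(config.branch_config, seed=int(child_seeds[i])))
        rng = np.random.default_rng(int(child_seeds[-1]))
        self.head = nn.Linear(config.fused_dim, config.num_classes, rng=rng, name="fused_head")

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for br in self.branches:
            ps.extend(br.trunk_params())  # branch heads are discarded
        ps.extend(self.head.params())
        return ps

    def forward(self, xs: list[np.ndarray], train: bool = False) -> np.ndarray:
        if len(xs) != len(self.branches):
            raise ValueError(f"expected {len(self.branches)} branch inputs, got {len(xs)}")
        for x, side in zip(xs, self.config.branch_sizes):
            if x.shape[-1] != side or x.shape[-2] != side:
                raise ValueError(
                    f"branch input side {x.shape[-1]} does not match configured {side}")
        feats = [br.features(x, train) for br, x in zip(self.branches, xs)]
        return self.head.forward(np.concatenate(feats, axis=1), train)

    __call__ = forward

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dim = self.config.branch_config.feature_dim
        for i, br in enumerate(self.branches):
            di = br.gap.backward(d[:, i * dim:(i + 1) * dim])
            for b in reversed(br.blocks):
                di = b.backward(di)


def build_srn(config: SRNConfig, seed: int = 0) -> SRN:
    """Instantiate an SRN from its config with seeded initialization."""
    return SRN(config, seed=seed)


def build_ms_srn(config: MultiScaleConfig, seed: int = 0) -> MSSRN:
    return MSSRN(config, seed=seed)


def count_parameters(network) -> ModelSummary:
    """Exact number of learnable scalars in a built network."""
    total = sum(p.size for p in network.params())
    return ModelSummary(parameter_count=total)


# ---------------------------------------------------------------------------
# Multiply–accumulate counting
# ---------------------------------------------------------------------------

def layer_macs(kernel_size: int, in_channels: int, out_channels: int,
               output_side: int) -> int:
    """MACs of one square conv layer: k^2 * Cin * Cout * output positions."""
    return kernel_size * kernel_size * in_channels * out_channels * output_side * output_side


def conv_stack_macs(kernels: list[int], channels: int, output_side: int = 1) -> int:
    """MACs of a channel-homogeneous conv stack (used for cost-ratio analysis)."""
    return sum(layer_macs(k, channels, channels, output_side) for k in kernels)


def _srn_macs(config: SRNConfig, input_side: int) -> int:
    _check_side(input_side)
    total = 0
    side = input_side
    c = config.in_channels
    for spec in config.blocks:
        for layer in spec.layers:
            total += layer_macs(layer.kernel_size, c, layer.out_channels, side)
            c = layer.out_channels
        if spec.followed_by_pool:
            side //= 2
    # projection convolutions
    side = input_side
    c_in = config.in_channels
    for spec in config.blocks:
        if spec.residual and c_in != spec.out_channels:
            total += layer_macs(1, c_in, spec.out_channels, side)
        c_in = spec.out_channels
        if spec.followed_by_pool:
            side //= 2
    total += config.feature_dim * config.num_classes  # head
    return total


def count_macs(network, input_side: int | None = None) -> int:
    """Multiply–accumulate count of a built network at a given input side.

    For a multi-scale model the configured branch sizes are used and
    ``input_side`` must be None.  This is a MAC count; printed "FLOPs"
    figures from other toolchains may differ by convention.
    """
    if isinstance(network, SRN):
        if input_side is None:
            raise ValueError("input_side is required for a single-scale network")
        return _srn_macs(network.config, input_side)
    if isinstance(network, MSSRN):
        if input_side is not None:
            raise ValueError("multi-scale networks use their configured branch sizes")
        cfg = network.config
        trunk = replace(cfg.branch_config)  # branch heads are discarded
        total = 0
        for side in cfg.branch_sizes:
            total += _srn_macs(trunk, side) - trunk.feature_dim * trunk.num_classes
        total += cfg.fused_dim * cfg.num_classes
        return total
    raise TypeError(f"cannot count MACs of {type(network).__name__}")


# ---------------------------------------------------------------------------
# Kernel factorization
# ---------------------------------------------------------------------------

def _receptive_field(kernels: tuple[int, ...]) -> int:
    return sum(k - 1 for k in kernels) + 1


def substitute_kernels(config: SRNConfig, rule: dict[int, tuple[int, ...]],
                       inverse: bool = False) -> SRNConfig:
    """Apply a kernel factorization rule, e.g. {5: (3, 3)}, to a config.

    Forward direction replaces each layer whose kernel appears in the rule
    by a stack of smaller-kernel layers with the same channel count (the
    receptive field is preserved: a 5x5 becomes two 3x3).  ``inverse=True``
    merges channel-homogeneous runs matching a rule's stack back into the
    single large kernel.  Output channel counts are never altered.
    """
    for big, stack in rule.items():
        stack = tuple(stack)
        if _receptive_field(stack) != big:
            raise ValueError(
                f"substitution {big} -> {stack} does not preserve the receptive field")
    new_blocks = []
    block_in = config.in_channels
    for spec in config.blocks:
        if not inverse:
            layers: list[LayerSpec] = []
            for layer in spec.layers:
                if layer.kernel_size in rule:
                    for k in rule[layer.kernel_size]:
                        layers.append(replace(layer, kernel_size=k))
                else:
                    layers.append(layer)
        else:
            layers = list(spec.layers)
            for big, stack in rule.items():
                stack = tuple(stack)
                merged: list[LayerSpec] = []
                i = 0
                c_in = block_in
                while i < len(layers):
                    run = layers[i:i + len(stack)]
                    homogeneous = (len(run) == len(stack)
                                   and all(l.kernel_size == k for l, k in zip(run, stack))
                                   and all(l.out_channels == c_in for l in run))
                    if homogeneous:
                        merged.append(replace(run[0], kernel_size=big))
                        i += len(stack)
                    else:
                        c_in = layers[i].out_channels
                        merged.append(layers[i])
                        i += 1
                layers = merged
        new_blocks.append(replace(spec, layers=tuple(layers)))
        block_in = spec.out_channels
    return replace(config, blocks=tuple(new_blocks))


# ---------------------------------------------------------------------------
# Reference residual-network parameter counts (standard topologies)
# ---------------------------------------------------------------------------

def _conv_bn(k: int, cin: int, cout: int) -> int:
    # reference nets use bias-free convs followed by batch norm (weight+bias)
    return k * k * cin * cout + 2 * cout


def count_reference_resnet(depth: int, num_classes: int = 4) -> ModelSummary:
    """Parameter count of the canonical 18- or 101-layer residual network
    with its final fully connected layer replaced by a ``num_classes`` output.
    """
    if depth == 18:
        stage_blocks, bottleneck = (2, 2, 2, 2), False
    elif depth == 101:
        stage_blocks, bottleneck = (3, 4, 23, 3), True
    else:
        raise ValueError(f"unsupported reference depth {depth}; choose 18 or 101")
    expansion = 4 if bottleneck else 1
    total = _conv_bn(7, 3, 64)  # stem
    cin = 64
    for stage, n_blocks in enumerate(stage_blocks):
        width = 64 * (2 ** stage)
        cout = width * expansion
        for b in range(n_blocks):
            if bottleneck:
                total += _conv_bn(1, cin, width) + _conv_bn(3, width, width) \
                    + _conv_bn(1, width, cout)
            else:
                total += _conv_bn(3, cin, cout) + _conv_bn(3, cout, cout)
            if b == 0 and cin != cout:
                total += _conv_bn(1, cin, cout)  # downsample projection
            cin = cout
    total += cin * num_classes + num_classes  # fc with bias
    return ModelSummary(parameter_count=total)
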