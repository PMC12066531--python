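"""Reference operators for RepConv and PConv/FasterBlock/C3-Faster blocks.

These are small, direct numpy implementations used as correctness oracles:
the point is algebraic fidelity (branch fusion that is *exactly* equivalent,
partial convolution whose untouched channels are bit-identical), not
throughput.  RepConv is multi-branch at train time — a 3×3 conv, a 1×1 conv
and an optional identity path, each batch-normalized — and collapses at
inference into one 3×3 convolution with bias by folding each BN into its
branch, centering the 1×1 kernel, expressing the identity as a Dirac kernel
and summing.  Parameter accounting for these blocks is included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class ConvParams:
    """Dense convolution parameters: kernel (out, in, k, k), optional bias."""

    kernel: np.ndarray
    bias: np.ndarray | None = None
    stride: int = 1

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel)
        if k.ndim != 4 or k.shape[2] != k.shape[3]:
            raise ValueError(f"kernel must be (out, in, k, k), got {k.shape}")
        if k.shape[2] not in (1, 3):
            raise ValueError(f"kernel size must be 1 or 3, got {k.shape[2]}")
        if self.bias is not None and np.asarray(self.bias).shape != (k.shape[0],):
            raise ValueError("bias shape must match output channels")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def out_channels(self) -> int:
        return self.kernel.shape[0]

    @property
    def in_channels(self) -> int:
        return self.kernel.shape[1]

    @property
    def kernel_size(self) -> int:
        return self.kernel.shape[2]


@dataclass(frozen=True)
class BNParams:
    """Batch-norm inference parameters (per output channel)."""

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    eps: float = 1e-5

    def __post_init__(self) -> None:
        n = np.asarray(self.gamma).shape
        for name in ("beta", "running_mean", "running_var"):
            if np.asarray(getattr(self, name)).shape != n:
                raise ValueError("BN parameter vectors must share one shape")
        if np.any(np.asarray(self.running_var) < 0):
            raise ValueError("running_var must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    @classmethod
    def identity(cls, channels: int) -> "BNParams":
        return cls(
            gamma=np.ones(channels),
            beta=np.zeros(channels),
            running_mean=np.zeros(channels),
            running_var=np.ones(channels),
            eps=1e-12,
        )


def conv2d(x: np.ndarray, params: ConvParams, padding: int = 0) -> np.ndarray:
    """Direct cross-correlation of a (ch, H, W) input. Reference path only."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"input must be (ch, H, W), got shape {x.shape}")
    if x.shape[0] != params.in_channels:
        raise ValueError(
            f"input has {x.shape[0]} channels, kernel expects {params.in_channels}"
        )
    k = params.kernel_size
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    if x.shape[1] < k or x.shape[2] < k:
        raise ValueError("input smaller than kernel after padding")
    # windows: (ch, H', W', k, k)
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, :: params.stride, :: params.stride]
    out = np.einsum("ihwkl,oikl->ohw", win, np.asarray(params.kernel, dtype=float))
    if params.bias is not None:
        out += np.asarray(params.bias, dtype=float)[:, None, None]
    return out


def batchnorm(x: np.ndarray, bn: BNParams) -> np.ndarray:
    """Inference-mode batch norm over the channel axis of (ch, H, W)."""
    scale = np.asarray(bn.gamma) / np.sqrt(np.asarray(bn.running_var) + bn.eps)
    shift = np.asarray(bn.beta) - np.asarray(bn.running_mean) * scale
    return x * scale[:, None, None] + shift[:, None, None]


@dataclass(frozen=True)
class RepConvBlock:
    """Train-time multi-branch RepConv: 3×3 + 1×1 (+ identity), each with BN."""

    conv3: ConvParams
    bn3: BNParams
    conv1: ConvParams
    bn1: BNParams
    bn_id: BNParams | None = None

    def __post_init__(self) -> None:
        if self.conv3.kernel_size != 3 or self.conv1.kernel_size != 1:
            raise ValueError("branches must be a 3x3 and a 1x1 convolution")
        if (
            self.conv3.out_channels != self.conv1.out_channels
            or self.conv3.in_channels != self.conv1.in_channels
        ):
            raise ValueError("branch channel shapes must agree")
        if self.bn_id is not None:
            if self.conv3.in_channels != self.conv3.out_channels:
                raise ValueError("identity branch requires in_channels == out_channels")
            if self.conv3.stride != 1:
                raise ValueError("identity branch requires stride 1")

    @property
    def channels(self) -> tuple[int, int]:
        return (self.conv3.in_channels, self.conv3.out_channels)


def repconv_forward_train(block: RepConvBlock, x: np.ndarray) -> np.ndarray:
    """Sum of the batch-normalized branch outputs (training topology)."""
    out = batchnorm(conv2d(x, block.conv3, padding=1), block.bn3)
    out = out + batchnorm(conv2d(x, block.conv1, padding=0), block.bn1)
    if block.bn_id is not None:
        out = out + batchnorm(np.asarray(x, dtype=float), block.bn_id)
    return out


def _fuse_conv_bn(kernel: np.ndarray, bn: BNParams) -> tuple[np.ndarray, np.ndarray]:
    var = np.asarray(bn.running_var, dtype=float)
    if np.any(var + bn.eps <= 0):
        raise ValueError("running_var + eps must be positive")
    scale = np.asarray(bn.gamma) / np.sqrt(var + bn.eps)
    fused_kernel = kernel * scale[:, None, None, None]
    fused_bias = np.asarray(bn.beta) - np.asarray(bn.running_mean) * scale
    return fused_kernel, fused_bias


def repconv_fuse(block: RepConvBlock) -> ConvParams:
    """Collapse the three branches into one 3×3 convolution with bias.

    Forward-equivalent to :func:`repconv_forward_train` (with padding 1) up
    to floating-point round-off.
    """
    k3, b3 = _fuse_conv_bn(np.asarray(block.conv3.kernel, float), block.bn3)
    k1, b1 = _fuse_conv_bn(np.asarray(block.conv1.kernel, float), block.bn1)
    k1 = np.pad(k1, ((0, 0), (0, 0), (1, 1), (1, 1)))  # center 1x1 into 3x3
    kernel = k3 + k1
    bias = b3 + b1
    if block.bn_id is not None:
        c = block.conv3.out_channels
        dirac = np.zeros((c, c, 3, 3))
        dirac[np.arange(c), np.arange(c), 1, 1] = 1.0
        kid, bid = _fuse_conv_bn(dirac, block.bn_id)
        kernel = kernel + kid
        bias = bias + bid
    return ConvParams(kernel=kernel, bias=bias, stride=block.conv3.stride)


def n_partial_channels(channels: int, ratio: float) -> int:
    """Channel count a PConv layer actually convolves: round(r·ch), at least 1."""
    cp = int(round(ratio * channels))
    return max(1, cp)


def pconv_forward(x: np.ndarray, params: ConvParams) -> np.ndarray:
    """Partial convolution: convolve the first c_p channels, pass the rest.

    ``params`` is a 3×3 convolution over c_p input channels producing c_p
    output channels; the remaining channels are copied through untouched, so
    spatial size and channel count are preserved.
    """
    x = np.asarray(x, dtype=float)
    cp = params.in_channels
    if params.out_channels != cp:
        raise ValueError("PConv kernel must map c_p channels to c_p channels")
    if cp > x.shape[0]:
        raise ValueError(f"c_p={cp} exceeds input channels {x.shape[0]}")
    out = x.copy()
    out[:cp] = conv2d(x[:cp], params, padding=params.kernel_size // 2)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


@dataclass(frozen=True)
class FasterBlock:
    """PConv followed by two pointwise convolutions, with a shortcut add."""

    pconv: ConvParams
    pw1: ConvParams
    pw2: ConvParams
    activation: Callable[[np.ndarray], np.ndarray] = relu

    def __post_init__(self) -> None:
        if self.pw1.kernel_size != 1 or self.pw2.kernel_size != 1:
            raise ValueError("pw1/pw2 must be pointwise (1x1)")
        if self.pw1.out_channels != self.pw2.in_channels:
            raise ValueError("pw1 output channels must feed pw2")


def faster_block_forward(x: np.ndarray, block: FasterBlock) -> np.ndarray:
    """x + pw2(act(pw1(pconv(x)))); requires matching in/out channels."""
    x = np.asarray(x, dtype=float)
    if block.pw1.in_channels != x.shape[0] or block.pw2.out_channels != x.shape[0]:
        raise ValueError("shortcut addition requires in_channels == out_channels")
    y = pconv_forward(x, block.pconv)
    y = conv2d(y, block.pw1)
    y = block.activation(y)
    y = conv2d(y, block.pw2)
    return x + y


@dataclass(frozen=True)
class C3FasterBlock:
    """C3 module with FasterBlocks in the main branch.

    Main branch: 1×1 conv, then ``n`` FasterBlocks; sub-branch: 1×1 conv on
    the input; the two are concatenated on channels and mixed by a final
    1×1 conv.
    """

    conv_main: ConvParams
    blocks: tuple[FasterBlock, ...]
    conv_sub: ConvParams
    conv_out: ConvParams


def c3_faster_forward(x: np.ndarray, module: C3FasterBlock) -> np.ndarray:
    main = conv2d(x, module.conv_main)
    for blk in module.blocks:
        main = faster_block_forward(main, blk)
    sub = conv2d(x, module.conv_sub)
    return conv2d(np.concatenate([main, sub], axis=0), module.conv_out)


def count_parameters(obj) -> int:
    """Learnable-parameter count of a ConvParams/BNParams/block or iterable.

    Convolution: k·k·c_in·c_out (+ c_out if biased); batch norm: 2·c_out
    (scale and shift; running statistics are buffers, not parameters).
    """
    if isinstance(obj, ConvParams):
        k = obj.kernel_size
        n = k * k * obj.in_channels * obj.out_channels
        return n + (obj.out_channels if obj.bias is not None else 0)
    if isinstance(obj, BNParams):
        return 2 * np.asarray(obj.gamma).size
    if isinstance(obj, RepConvBlock):
        parts = [obj.conv3, obj.bn3, obj.conv1, obj.bn1]
        if obj.bn_id is not None:
            parts.append(obj.bn_id)
        return sum(count_parameters(p) for p in parts)
    if isinstance(obj, FasterBlock):
        return sum(count_parameters(p) for p in (obj.pconv, obj.pw1, obj.pw2))
    if isinstance(obj, C3FasterBlock):
        return (
            count_parameters(obj.conv_main)
            + sum(count_parameters(b) for b in obj.blocks)
            + count_parameters(obj.conv_sub)
            + count_parameters(obj.conv_out)
        )
    if isinstance(obj, Sequence):
        return sum(count_parameters(p) for p in obj)
    raise TypeError(f"cannot count parameters of {type(obj).__name__}")


def percent_reduction(before: int, after: int) -> float:
    """Relative parameter reduction in percent, one decimal: 100·(1 − after/before)."""
    if before <= 0:
        raise ValueError("baseline count must be positive")
    return round(100.0 * (before - after) / before, 1)


def random_repconv_block(
    rng: np.random.Generator,
    in_channels: int,
    out_channels: int,
    identity: bool | None = None,
    stride: int = 1,
) -> RepConvBlock:
    """Random valid block for equivalence testing and demos."""

    def bn(c: int) -> BNParams:
        return BNParams(
            gamma=rng.normal(1.0, 0.2, c),
            beta=rng.normal(0.0, 0.2, c),
            running_mean=rng.normal(0.0, 0.5, c),
            running_var=rng.uniform(0.2, 2.0, c),
        )

    if identity is None:
        identity = in_channels == out_channels and stride == 1
    return RepConvBlock(
        conv3=ConvParams(rng.normal(size=(out_channels, in_channels, 3, 3)), stride=stride),
        bn3=bn(out_channels),
        conv1=ConvParams(rng.normal(size=(out_channels, in_channels, 1, 1)), stride=stride),
        bn1=bn(out_channels),
        bn_id=bn(out_channels) if identity else None,
    )
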