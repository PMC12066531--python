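"""Convolution oracle, RepConv fusion equivalence, PConv/FasterBlock contracts."""

import numpy as np
import pytest

from planterkit.blocks import (
    BNParams,
    C3FasterBlock,
    ConvParams,
    FasterBlock,
    RepConvBlock,
    c3_faster_forward,
    conv2d,
    count_parameters,
    faster_block_forward,
    n_partial_channels,
    pconv_forward,
    percent_reduction,
    random_repconv_block,
    relu,
    repconv_forward_train,
    repconv_fuse,
)


def naive_conv2d(x, kernel, bias=None, padding=0):
    """Quadruple-loop sliding-window reference, deliberately dumb."""
    co, ci, k, _ = kernel.shape
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    H, W = x.shape[1] - k + 1, x.shape[2] - k + 1
    out = np.zeros((co, H, W))
    for o in range(co):
        for i in range(H):
            for j in range(W):
                out[o, i, j] = np.sum(x[:, i : i + k, j : j + k] * kernel[o])
        if bias is not None:
            out[o] += bias[o]
    return out


class TestConv2d:
    def test_identity_kernel(self, rng):
        x = rng.normal(size=(3, 6, 6))
        kernel = np.eye(3).reshape(3, 3, 1, 1)
        np.testing.assert_allclose(conv2d(x, ConvParams(kernel)), x)

    def test_zero_kernel(self, rng):
        x = rng.normal(size=(2, 5, 5))
        out = conv2d(x, ConvParams(np.zeros((4, 2, 3, 3))), padding=1)
        assert out.shape == (4, 5, 5)
        assert not out.any()

    def test_matches_naive_loop(self, rng):
        x = rng.normal(size=(2, 4, 4))
        kernel = rng.normal(size=(3, 2, 3, 3))
        bias = rng.normal(size=3)
        got = conv2d(x, ConvParams(kernel, bias), padding=1)
        np.testing.assert_allclose(got, naive_conv2d(x, kernel, bias, padding=1), atol=1e-10)

    def test_stride(self, rng):
        x = rng.normal(size=(1, 6, 6))
        kernel = rng.normal(size=(1, 1, 3, 3))
        got = conv2d(x, ConvParams(kernel, stride=2), padding=1)
        full = conv2d(x, ConvParams(kernel), padding=1)
        np.testing.assert_allclose(got, full[:, ::2, ::2])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            conv2d(rng.normal(size=(2, 5, 5)), ConvParams(np.zeros((1, 3, 3, 3))))

    def test_kernel_size_validated(self):
        with pytest.raises(ValueError):
            ConvParams(np.zeros((1, 1, 5, 5)))


class TestRepConv:
    def test_identity_branch_only_passes_input(self, rng):
        c = 3
        block = RepConvBlock(
            conv3=ConvParams(np.zeros((c, c, 3, 3))),
            bn3=BNParams.identity(c),
            conv1=ConvParams(np.zeros((c, c, 1, 1))),
            bn1=BNParams.identity(c),
            bn_id=BNParams.identity(c),
        )
        x = rng.normal(size=(c, 5, 5))
        np.testing.assert_allclose(repconv_forward_train(block, x), x, atol=1e-9)

    def test_reduces_to_bn_conv3_without_identity(self, rng):
        c = 2
        k3 = rng.normal(size=(c, c, 3, 3))
        block = RepConvBlock(
            conv3=ConvParams(k3),
            bn3=BNParams.identity(c),
            conv1=ConvParams(np.zeros((c, c, 1, 1))),
            bn1=BNParams.identity(c),
        )
        x = rng.normal(size=(c, 6, 6))
        np.testing.assert_allclose(
            repconv_forward_train(block, x),
            conv2d(x, ConvParams(k3), padding=1),
            atol=1e-9,
        )

    def test_train_form_is_branch_sum(self, rng):
        from planterkit.blocks import batchnorm

        block = random_repconv_block(rng, 3, 3)
        x = rng.normal(size=(3, 7, 7))
        expected = (
            batchnorm(conv2d(x, block.conv3, padding=1), block.bn3)
            + batchnorm(conv2d(x, block.conv1), block.bn1)
            + batchnorm(x, block.bn_id)
        )
        np.testing.assert_allclose(repconv_forward_train(block, x), expected)

    def test_fused_identity_block_is_dirac(self):
        c = 4
        block = RepConvBlock(
            conv3=ConvParams(np.zeros((c, c, 3, 3))),
            bn3=BNParams.identity(c),
            conv1=ConvParams(np.zeros((c, c, 1, 1))),
            bn1=BNParams.identity(c),
            bn_id=BNParams.identity(c),
        )
        fused = repconv_fuse(block)
        expected = np.zeros((c, c, 3, 3))
        expected[np.arange(c), np.arange(c), 1, 1] = 1.0
        np.testing.assert_allclose(fused.kernel, expected, atol=1e-9)
        np.testing.assert_allclose(fused.bias, np.zeros(c), atol=1e-9)

    @pytest.mark.parametrize("cin,cout,identity", [(2, 2, True), (3, 3, False), (2, 5, False)])
    def test_fusion_forward_equivalence(self, rng, cin, cout, identity):
        block = random_repconv_block(rng, cin, cout, identity=identity)
        fused = repconv_fuse(block)
        for _ in range(5):
            x = rng.normal(size=(cin, 9, 9))
            err = np.abs(
                repconv_forward_train(block, x) - conv2d(x, fused, padding=1)
            ).max()
            assert err < 1e-6

    def test_fused_has_fewer_parameters(self, rng):
        block = random_repconv_block(rng, 4, 4)
        assert count_parameters(repconv_fuse(block)) < count_parameters(block)

    def test_identity_branch_requires_square_channels(self):
        with pytest.raises(ValueError, match="identity"):
            RepConvBlock(
                conv3=ConvParams(np.zeros((3, 2, 3, 3))),
                bn3=BNParams.identity(3),
                conv1=ConvParams(np.zeros((3, 2, 1, 1))),
                bn1=BNParams.identity(3),
                bn_id=BNParams.identity(3),
            )


class TestPConv:
    def test_full_ratio_is_ordinary_conv(self, rng):
        x = rng.normal(size=(4, 6, 6))
        kernel = rng.normal(size=(4, 4, 3, 3))
        np.testing.assert_allclose(
            pconv_forward(x, ConvParams(kernel)),
            conv2d(x, ConvParams(kernel), padding=1),
        )

    def test_identity_kernel_is_identity(self, rng):
        x = rng.normal(size=(8, 5, 5))
        cp = n_partial_channels(8, 0.25)
        kernel = np.zeros((cp, cp, 3, 3))
        kernel[np.arange(cp), np.arange(cp), 1, 1] = 1.0
        np.testing.assert_allclose(pconv_forward(x, ConvParams(kernel)), x)

    def test_passthrough_channels_bit_identical(self, rng):
        x = rng.normal(size=(8, 5, 5))
        cp = 2
        out = pconv_forward(x, ConvParams(rng.normal(size=(cp, cp, 3, 3))))
        assert (out[cp:] == x[cp:]).all()

    def test_cp_exceeding_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="c_p"):
            pconv_forward(rng.normal(size=(2, 5, 5)), ConvParams(np.zeros((4, 4, 3, 3))))

    def test_partial_channel_rounding(self):
        assert n_partial_channels(8, 0.25) == 2
        assert n_partial_channels(3, 0.25) == 1  # never zero


class TestFasterBlock:
    def _block(self, rng, c=4, cp=1, hidden=8, zero=False):
        draw = (lambda *s: np.zeros(s)) if zero else (lambda *s: rng.normal(size=s))
        return FasterBlock(
            pconv=ConvParams(draw(cp, cp, 3, 3)),
            pw1=ConvParams(draw(hidden, c, 1, 1)),
            pw2=ConvParams(draw(c, hidden, 1, 1)),
        )

    def test_zero_weights_shortcut_only(self, rng):
        x = rng.normal(size=(4, 5, 5))
        np.testing.assert_allclose(faster_block_forward(x, self._block(rng, zero=True)), x)

    def test_composition_matches_manual_chaining(self, rng):
        block = self._block(rng)
        x = rng.normal(size=(4, 6, 6))
        manual = x + conv2d(relu(conv2d(pconv_forward(x, block.pconv), block.pw1)), block.pw2)
        np.testing.assert_allclose(faster_block_forward(x, block), manual)

    def test_shape_preserved(self, rng):
        x = rng.normal(size=(4, 7, 9))
        assert faster_block_forward(x, self._block(rng)).shape == x.shape

    def test_channel_mismatch_rejected(self, rng):
        block = FasterBlock(
            pconv=ConvParams(rng.normal(size=(1, 1, 3, 3))),
            pw1=ConvParams(rng.normal(size=(8, 4, 1, 1))),
            pw2=ConvParams(rng.normal(size=(3, 8, 1, 1))),  # 4 in, 3 out
        )
        with pytest.raises(ValueError, match="shortcut"):
            faster_block_forward(rng.normal(size=(4, 5, 5)), block)

    def test_c3_faster_output_shape(self, rng):
        c, half = 8, 4
        inner = FasterBlock(
            pconv=ConvParams(rng.normal(size=(1, 1, 3, 3))),
            pw1=ConvParams(rng.normal(size=(8, half, 1, 1))),
            pw2=ConvParams(rng.normal(size=(half, 8, 1, 1))),
        )
        module = C3FasterBlock(
            conv_main=ConvParams(rng.normal(size=(half, c, 1, 1))),
            blocks=(inner, inner),
            conv_sub=ConvParams(rng.normal(size=(half, c, 1, 1))),
            conv_out=ConvParams(rng.normal(size=(c, 2 * half, 1, 1))),
        )
        x = rng.normal(size=(c, 6, 6))
        assert c3_faster_forward(x, module).shape == (c, 6, 6)


class TestParameterAccounting:
    def test_conv_with_bn(self):
        conv = ConvParams(np.zeros((32, 16, 3, 3)))
        assert count_parameters(conv) == 4608
        assert count_parameters([conv, BNParams.identity(32)]) == 4672

    def test_pointwise_with_bias(self):
        conv = ConvParams(np.zeros((8, 8, 1, 1)), bias=np.zeros(8))
        assert count_parameters(conv) == 72

    def test_fused_repconv_count(self, rng):
        c = 6
        fused = repconv_fuse(random_repconv_block(rng, c, c))
        assert count_parameters(fused) == 9 * c * c + c

    def test_percent_reduction(self):
        assert percent_reduction(1000, 500) == 50.0
        with pytest.raises(ValueError):
            percent_reduction(0, 5)
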