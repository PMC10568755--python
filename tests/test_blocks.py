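"""Unit and property tests for the network blocks."""
import numpy as np
import pytest

from peapod.autograd import Tensor, no_grad
from peapod.blocks import (CARAFE, CBS, DBS, SPPF, CoordAtt, C2f, ConfigError,
                           Detect, GhostBottleneck, GhostConv, PCC)
from peapod.nn import Conv2d, seed_init

RNG = np.random.default_rng(11)


def fwd(block, x):
    block.eval()
    with no_grad():
        return block(Tensor(x)).data


def conv_weights(block):
    """Total convolution weight scalars (excluding BN and biases)."""
    return sum(m.weight.size for m in block.modules() if isinstance(m, Conv2d))


def rand(*shape):
    return RNG.standard_normal(shape).astype(np.float32)


class TestCBSandDBS:
    def test_stride_and_shape(self):
        y = fwd(CBS(3, 16, 3, 2), rand(1, 3, 64, 64))
        assert y.shape == (1, 16, 32, 32)
        y = fwd(CBS(16, 16, 1, 1), rand(1, 16, 8, 8))
        assert y.shape == (1, 16, 8, 8)

    def test_weight_counts(self):
        assert conv_weights(CBS(3, 16, 3, 2)) == 3 * 9 * 16 == 432
        # grouped downsample: groups = gcd -> k^2 * (c_in/M) * c_out weights
        assert conv_weights(DBS(64, 128, 3, 2)) == 9 * (64 // 64) * 128 == 1152
        assert conv_weights(DBS(64, 64, 3, 1)) == 9 * 1 * 64 == 576

    def test_invalid_dims_raise(self):
        with pytest.raises(ConfigError):
            CBS(0, 16, 3)


class TestGhost:
    def test_weight_counts_and_shape(self):
        g = GhostConv(16, 32, 1, cheap_k=5)
        assert g.primary.conv.weight.size == 16 * 16 == 256
        assert g.cheap.conv.weight.size == 16 * 25 == 400
        assert conv_weights(g) == 656
        assert fwd(g, rand(1, 16, 8, 8)).shape == (1, 32, 8, 8)

    def test_concatenation_order(self):
        g = GhostConv(8, 16, 1)
        g.eval()
        x = Tensor(rand(1, 8, 6, 6))
        with no_grad():
            full = g(x).data
            primary = g.primary(x).data
        assert np.allclose(full[:, :8], primary)

    def test_odd_out_channels_rejected(self):
        with pytest.raises(ConfigError):
            GhostConv(8, 15)

    def test_bottleneck_residual_identity_with_zero_weights(self):
        b = GhostBottleneck(16, shortcut=True)
        for p in b.parameters():
            p.data[:] = 0.0
        x = rand(1, 16, 8, 8)
        assert np.allclose(fwd(b, x), x)

    def test_bottleneck_shape_and_frozen_count(self):
        b = GhostBottleneck(32, cheap_k=5, primary_k=3)
        assert fwd(b, rand(1, 32, 16, 16)).shape == (1, 32, 16, 16)
        # enumeration oracle, computed by hand from the two GhostConvs:
        # g1: primary 3x3 32->8 (2304 w + 16 bn) + cheap 5x5 dw on 8 (200 + 16)
        # g2: primary 1x1 16->16 (256 + 32) + cheap 5x5 dw on 16 (400 + 32)
        assert b.num_params() == (2304 + 16 + 200 + 16) + (256 + 32 + 400 + 32)


class TestC2f:
    @pytest.mark.parametrize("ghost", [False, True])
    def test_shape(self, ghost):
        blk = C2f(32, 32, n=1, ghost=ghost)
        assert fwd(blk, rand(1, 32, 16, 16)).shape == (1, 32, 16, 16)

    def test_ghost_reduces_params(self):
        dense = C2f(32, 32, n=2)
        ghost = C2f(32, 32, n=2, ghost=True)
        assert ghost.num_params() < dense.num_params()

    def test_ghost_frozen_count(self):
        blk = C2f(32, 32, n=1, ghost=True, ghost_primary_k=3, ghost_cheap_k=3)
        # cv1: 32->32 1x1 (1024+64); cv2: 48->32 1x1 (1536+64);
        # ghost bottleneck on c=16: g1 primary 3x3 16->4 (576+8) + dw3 on 4
        # (36+8); g2 primary 1x1 8->8 (64+16) + dw3 on 8 (72+16)
        assert blk.num_params() == (1024 + 64) + (1536 + 64) + \
            (576 + 8 + 36 + 8) + (64 + 16 + 72 + 16)


class TestSPPF:
    def test_shape_and_constant(self):
        s = SPPF(64, 64)
        assert fwd(s, rand(1, 64, 10, 10)).shape == (1, 64, 10, 10)
        s = SPPF(8, 8)
        x = np.tile(np.arange(8, dtype=np.float32).reshape(1, 8, 1, 1), (1, 1, 6, 6))
        s.eval()
        with no_grad():
            y = s(Tensor(x)).data
        # constant per-channel input stays constant per channel
        assert np.allclose(y, y[:, :, :1, :1], atol=1e-5)

    def test_chained_pools_equal_single_wide_pool(self):
        # two same-padded 5-pools have the receptive field of one 9-pool
        x = Tensor(np.cumsum(rand(1, 2, 1, 12), axis=3))  # monotone ramp
        twice = x.maxpool2d(5, 1, 2).maxpool2d(5, 1, 2).data
        once = x.maxpool2d(9, 1, 4).data
        assert np.allclose(twice, once)


class TestCoordAtt:
    def test_shape(self):
        assert fwd(CoordAtt(32), rand(1, 32, 8, 8)).shape == (1, 32, 8, 8)

    def test_constant_input_gives_proportional_output(self):
        ca = CoordAtt(16)
        x = np.tile(rand(1, 16, 1, 1), (1, 1, 6, 6))
        y = fwd(ca, x)
        ratio = y / np.where(np.abs(x) > 1e-6, x, 1.0)
        # attention maps are spatially constant, so the ratio is per-channel
        assert np.allclose(ratio, ratio[:, :, :1, :1], atol=1e-5)

    def test_saturated_gates_pass_input_through(self):
        ca = CoordAtt(8)
        ca.conv_h.bias.data[:] = 50.0
        ca.conv_w.bias.data[:] = 50.0
        x = rand(1, 8, 5, 5)
        assert np.allclose(fwd(ca, x), x, atol=1e-4)


class TestCARAFE:
    def test_encoder_channels_and_shape(self):
        up = CARAFE(64, sigma=2, k_up=3, k_encoder=5)
        assert up.encoder.c_out == 4 * 9 == 36
        assert fwd(up, rand(1, 64, 8, 8)).shape == (1, 64, 16, 16)

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            CARAFE(64, k_up=4)

    def test_uniform_kernel_averages_neighbourhood(self):
        # zero encoder weights -> softmax gives the uniform 1/k^2 kernel
        up = CARAFE(1, sigma=2, k_up=3, k_encoder=3, c_mid=4)
        up.encoder.weight.data[:] = 0.0
        img = np.arange(25, dtype=np.float32).reshape(1, 1, 5, 5)
        y = fwd(up, img)
        # brute-force averaging oracle with edge-replicated borders
        pad = np.pad(img[0, 0], 1, mode="edge")
        for i in range(10):
            for j in range(10):
                si, sj = i // 2, j // 2
                want = pad[si:si + 3, sj:sj + 3].mean()
                assert abs(y[0, 0, i, j] - want) < 1e-5

    def test_softmax_kernels_sum_to_one_and_preserve_constants(self):
        up = CARAFE(8, sigma=2, k_up=3, k_encoder=5, c_mid=16)
        x = np.full((1, 8, 6, 6), 3.25, dtype=np.float32)
        y = fwd(up, x)
        assert np.allclose(y, 3.25, atol=1e-5)

    def test_sigmoid_normalizer_breaks_constant_reproduction(self):
        up = CARAFE(8, normalizer="sigmoid", c_mid=16)
        x = np.full((1, 8, 6, 6), 1.0, dtype=np.float32)
        assert not np.allclose(fwd(up, x), 1.0, atol=1e-3)


class TestPCC:
    def test_weight_counts(self):
        p = PCC(64, r=4, k=3)
        assert p.g_partial.conv.weight.size == 9 * 16 * 16 == 2304
        assert p.g_fuse.conv.weight.size == 64 * 64 == 4096
        assert conv_weights(p) == 6400

    def test_shape_and_divisibility(self):
        assert fwd(PCC(64), rand(1, 64, 8, 8)).shape == (1, 64, 8, 8)
        with pytest.raises(ConfigError):
            PCC(10, r=4)

    def test_r_equal_one_degenerates_to_full_conv_pair(self):
        p = PCC(16, r=1, k=3)
        assert p.g_partial.conv.weight.shape == (16, 16, 3, 3)
        assert fwd(p, rand(1, 16, 6, 6)).shape == (1, 16, 6, 6)


class TestDetect:
    def shapes(self, head):
        feats = [Tensor(rand(1, c, s, s)) for c, s in ((64, 8), (128, 4), (256, 2))]
        head.eval()
        with no_grad():
            return [o.shape for o in head(feats)]

    def test_prediction_map_shapes(self):
        for pcc in (False, True):
            head = Detect([64, 128, 256], num_classes=2, pcc=pcc)
            assert self.shapes(head) == [(1, 66, 8, 8), (1, 66, 4, 4), (1, 66, 2, 2)]

    def test_pcc_head_smaller_than_standard(self):
        std = Detect([64, 128, 256], num_classes=2, pcc=False)
        pcc = Detect([64, 128, 256], num_classes=2, pcc=True)
        assert pcc.num_params() < std.num_params()

    def test_pcc_head_frozen_count(self):
        seed_init(0)
        head = Detect([64, 128, 256], num_classes=2, pcc=True)
        # enumeration oracle: per level, per branch: 1x1 entry CBS(c->64),
        # two PCC(64, r=4, k=3) and a biased 1x1 prediction conv, + 16 for
        # the fixed distribution-expectation filter
        pcc_unit = (2304 + 32) + (4096 + 128)
        total = 16
        for c in (64, 128, 256):
            entry = c * 64 + 128
            total += 2 * entry + 4 * pcc_unit + (64 * 64 + 64) + (64 * 2 + 2)
        assert head.num_params() == total == 149718

    def test_wrong_level_count_rejected(self):
        with pytest.raises(ConfigError):
            Detect([64, 128], num_classes=2)


def test_blocks_preserve_batch_independence():
    """Permuting batch elements commutes with a representative block stack."""
    blk = C2f(8, 8, n=1, ghost=True)
    x = rand(3, 8, 6, 6)
    perm = [2, 0, 1]
    y = fwd(blk, x)
    y_perm = fwd(blk, x[perm])
    assert np.allclose(y[perm], y_perm, atol=1e-5)
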