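"""Architecture oracles for the deblurring network."""

import numpy as np
import pytest

from deblurseg import nn
from deblurseg.nn import functional as F
from deblurseg.nn.tensor import Tensor
from deblurseg.restorer import (AttentionGate, ConvStem, DecoderBlock,
                                DeformResBlock, Downsample, DSBlock, DSGroup,
                                MotionDeblurNet, OutputHead, RestorerConfig,
                                WideAttentionBlock, expected_parameter_count)

C = 8


@pytest.fixture
def cfg():
    return RestorerConfig(channels=C, levels=2)


def rand_feat(rng, c=C, h=12, w=12, n=1):
    return Tensor(rng.normal(size=(n, c, h, w)))


class TestBlocks:
    def test_stem_shape_and_nonnegativity(self, cfg, rng):
        stem = ConvStem(cfg, rng=rng)
        out = stem(Tensor(rng.uniform(-1, 1, size=(2, 3, 16, 20))))
        assert out.data.shape == (2, C, 16, 20)
        assert (out.data >= 0).all()
        with pytest.raises(ValueError):
            stem(rand_feat(rng, c=4))

    def test_stem_parameter_count(self, cfg, rng):
        stem = ConvStem(cfg, rng=rng)
        convs = 3 * 3 * 3 * C + C + 3 * 3 * C * C + C
        norms = 2 * (2 * C)
        assert stem.count_parameters() == convs + norms

    def test_dsblock_conv_parameter_count(self, rng):
        """Separable factorization costs C^2 + 9C conv weights."""
        block = DSBlock(C, rng=rng, norm=False)
        assert block.count_parameters() == C * C + 9 * C
        full = DSBlock(C, rng=rng)
        assert full.count_parameters() == C * C + 9 * C + 2 * C

    def test_dsblock_impulse_confined_to_3x3(self, rng):
        """One application touches at most a 3x3 neighborhood."""
        block = DSBlock(C, rng=rng, norm=False)
        x = np.zeros((1, C, 15, 15))
        x[0, :, 7, 7] = 1.0
        out = block(Tensor(x)).data
        support = np.abs(out).sum(axis=(0, 1)) > 1e-12
        ys, xs = np.where(support)
        assert ys.min() >= 6 and ys.max() <= 8
        assert xs.min() >= 6 and xs.max() <= 8

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_group_receptive_field_is_1_plus_2n(self, n, rng):
        """Impulse response of a depth-n chain spans (1+2n) pixels."""
        group = DSGroup(C, n, rng=rng, norm=False)
        x = np.zeros((1, C, 21, 21))
        x[0, :, 10, 10] = 1.0
        out = group(Tensor(x)).data
        support = np.abs(out).sum(axis=(0, 1)) > 1e-12
        ys, xs = np.where(support)
        width = 1 + 2 * n
        assert ys.max() - ys.min() + 1 == width
        assert xs.max() - xs.min() + 1 == width

    def test_group_parameter_count(self, rng):
        for n in (1, 3):
            group = DSGroup(C, n, rng=rng)
            assert group.count_parameters() == n * (C * C + 9 * C + 2 * C)
        with pytest.raises(ValueError):
            DSGroup(C, 0, rng=rng)

    def test_attention_gate_bounds_and_zero_input(self, rng):
        gate = AttentionGate(C, C, rng=rng)
        x = rand_feat(rng)
        out = gate(x).data
        nz = x.data != 0
        assert (np.abs(out)[nz] < np.abs(x.data)[nz]).all()
        assert (gate(Tensor(np.zeros((1, C, 4, 4)))).data == 0).all()

    def test_attention_gate_half_weight_when_second_conv_zeroed(self, rng):
        """sigmoid(0) = 0.5, so zeroing conv2 halves the input exactly."""
        gate = AttentionGate(C, C, rng=rng)
        gate.conv2.weight.data[:] = 0.0
        gate.conv2.bias.data[:] = 0.0
        x = rand_feat(rng)
        np.testing.assert_allclose(gate(x).data, 0.5 * x.data, atol=1e-12)

    def test_wide_block_alpha_zero_equals_attention_branch(self, cfg, rng):
        """At init the learnable skip contributes nothing."""
        block = WideAttentionBlock(cfg, rng=rng)
        assert (block.alpha.data == 0).all()
        x = rand_feat(rng)
        att = block.gate(block.feature_extract(x))
        np.testing.assert_allclose(block(x).data, att.data, atol=1e-12)

    def test_wide_block_alpha_one_with_zeroed_convs_is_identity(self, cfg, rng):
        block = WideAttentionBlock(cfg, rng=rng)
        block.alpha.data[:] = 1.0
        block.fuse.weight.data[:] = 0.0
        # fe is then a constant zero map -> gate output 0 -> pure skip
        x = rand_feat(rng)
        np.testing.assert_allclose(block(x).data, x.data, atol=1e-12)

    def test_wide_block_concat_width(self, cfg, rng):
        block = WideAttentionBlock(cfg, rng=rng)
        assert block.fuse.in_channels == 4 * C

    def test_downsample_halves_dims_and_averages(self, rng):
        down = Downsample(C, rng=rng)
        x = rand_feat(rng, h=16, w=16)
        assert down(x).data.shape == (1, C, 8, 8)
        # all-equal taps of 1/4 reproduce 2x2 average pooling
        down.conv.weight.data[:] = 0.0
        for c in range(C):
            down.conv.weight.data[c, c] = 0.25
        down.conv.bias.data[:] = 0.0
        got = down(x).data
        want = x.data.reshape(1, C, 8, 2, 8, 2).mean(axis=(3, 5))
        np.testing.assert_allclose(got, want, atol=1e-12)
        with pytest.raises(ValueError):
            down(rand_feat(rng, h=7, w=8))

    def test_deform_resblock_matches_plain_resblock_at_init(self, rng):
        """Zero offsets / unit modulation: the block is a standard conv
        resblock with the same weights."""
        block = DeformResBlock(C, rng=rng)
        x = rand_feat(rng, h=8, w=8)
        got = block(x).data
        inner = F.conv2d(x, block.deform.weight,
                         block.deform.bias, padding=1).relu()
        want = (block.conv(inner) + x).data
        np.testing.assert_allclose(got, want, atol=1e-5)

    def test_deform_resblock_zeroed_weights_is_identity(self, rng):
        block = DeformResBlock(C, rng=rng)
        block.deform.weight.data[:] = 0.0
        block.deform.bias.data[:] = 0.0
        block.conv.weight.data[:] = 0.0
        block.conv.bias.data[:] = 0.0
        x = rand_feat(rng)
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_decoder_block_shapes(self, rng):
        dec = DecoderBlock(C, rng=rng)
        prev = rand_feat(rng, h=6, w=6)
        skip = rand_feat(rng, h=12, w=12)
        assert dec(prev, skip).data.shape == skip.data.shape
        with pytest.raises(ValueError):
            dec(prev, rand_feat(rng, h=10, w=10))

    def test_output_head_channel_taper(self, rng):
        head = OutputHead(RestorerConfig(channels=128, levels=1), rng=rng)
        assert head.conv1.weight.data.shape[:2] == (64, 128)
        assert head.conv2.weight.data.shape[:2] == (32, 64)
        assert head.conv3.weight.data.shape[:2] == (3, 32)

    def test_output_head_zero_init_emits_zero_residual(self, cfg, rng):
        head = OutputHead(cfg, rng=rng)
        out = head(rand_feat(rng))
        np.testing.assert_array_equal(out.data, 0.0)


class TestNetwork:
    def test_restore_shape_and_open_interval_range(self, cfg, rng):
        net = MotionDeblurNet(cfg, seed=0)
        img = rng.uniform(-1, 1, size=(24, 24, 3))
        out = net.restore(img)
        assert out.shape == (24, 24, 3)
        assert (np.abs(out) < 1.0).all()

    def test_initial_network_is_tanh_passthrough(self, cfg, rng):
        """Zero-initialized head makes restore(x) = tanh(x) exactly."""
        net = MotionDeblurNet(cfg, seed=1)
        img = rng.uniform(-1, 1, size=(16, 16, 3))
        np.testing.assert_allclose(net.restore(img), np.tanh(img), atol=1e-12)

    def test_encoder_skip_resolutions(self, rng):
        net = MotionDeblurNet(RestorerConfig(channels=8, levels=3), seed=0)
        x = Tensor(rng.uniform(-1, 1, size=(1, 3, 32, 32)))
        skips = net.encode(x)
        assert [s.data.shape[2] for s in skips] == [32, 16, 8]

    def test_single_level_network_has_no_decoder(self, rng):
        net = MotionDeblurNet(RestorerConfig(channels=8, levels=1), seed=0)
        assert len(net.decoders.layers) == 0
        out = net.restore(rng.uniform(-1, 1, size=(11, 13, 3)))
        assert out.shape == (11, 13, 3)

    def test_indivisible_input_rejected(self, cfg):
        net = MotionDeblurNet(cfg, seed=0)
        with pytest.raises(ValueError):
            net.restore(np.zeros((15, 16, 3)))
        with pytest.raises(ValueError):
            net.restore(np.full((16, 16, 3), 1.5))

    @pytest.mark.parametrize("kwargs", [
        dict(channels=8, levels=1),
        dict(channels=8, levels=2),
        dict(channels=16, levels=3, group_sizes=(1, 2)),
        dict(channels=12, levels=2, attention_hidden=4),
        dict(channels=128, levels=3),
    ])
    def test_parameter_count_matches_closed_form(self, kwargs):
        cfg = RestorerConfig(**kwargs)
        net = MotionDeblurNet(cfg, seed=0)
        assert net.count_parameters() == expected_parameter_count(cfg)

    def test_norm_placement_encoder_instance_decoder_batch(self, cfg):
        """Winning configuration: instance norm everywhere upstream of the
        decoder, batch norm inside it."""
        net = MotionDeblurNet(cfg, seed=0)
        enc_side = [net.stem, net.enc_blocks, net.enc_refine, net.downs]
        for region in enc_side:
            kinds = {type(m) for m in region.modules()}
            assert nn.BatchNorm2d not in kinds
        dec_norms = {type(m) for m in net.decoders.modules()
                     if isinstance(m, (nn.BatchNorm2d, nn.InstanceNorm2d))}
        assert dec_norms == {nn.BatchNorm2d}

    def test_invalid_configurations_rejected(self):
        with pytest.raises(ValueError):
            RestorerConfig(channels=6)
        with pytest.raises(ValueError):
            RestorerConfig(levels=0)
        with pytest.raises(ValueError):
            RestorerConfig(group_sizes=())

    def test_checkpoint_round_trip(self, tmp_path, cfg, rng):
        from deblurseg import io
        net = MotionDeblurNet(cfg, seed=3)
        io.save_checkpoint(net, tmp_path / "ckpt")
        loaded = io.load_restorer(tmp_path / "ckpt")
        img = rng.uniform(-1, 1, size=(16, 16, 3))
        np.testing.assert_array_equal(net.restore(img), loaded.restore(img))
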