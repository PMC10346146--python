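"""Encoder/decoder contracts and the composed network."""

import numpy as np
import pytest

from rfeunet import (Decoder, Encoder, EncoderOutput, LossWeights, RFEUNet, ShapeError,
                     decoder_forward, encoder_forward, mixed_loss_graph, rfe_unet_forward)
from rfeunet.nn import SGD, Tensor

WIDTHS = (8, 16, 32, 64)


@pytest.fixture(scope="module")
def tiny_net():
    return RFEUNet(resolution=32, widths=WIDTHS, rfe_layers=1, units_per_stage=1, seed=0)


class TestEncoder:
    def test_stride_arithmetic_and_channels(self, rng):
        enc = Encoder(widths=WIDTHS, rng=rng)
        out = encoder_forward(enc, rng.normal(size=(3, 32, 32)).astype(np.float32))
        assert out.bottleneck.shape == (1, 64, 2, 2)
        assert [s.shape[2] for s in out.skips] == [16, 8, 4]
        assert [s.shape[1] for s in out.skips] == [8, 16, 32]

    def test_channel_progression_increases(self, rng):
        enc = Encoder(widths=WIDTHS, rng=rng)
        out = encoder_forward(enc, rng.normal(size=(3, 32, 32)).astype(np.float32))
        channels = [s.shape[1] for s in out.skips] + [out.bottleneck.shape[1]]
        assert channels == sorted(channels) and len(set(channels)) == 4

    def test_indivisible_input_rejected(self, rng):
        enc = Encoder(widths=WIDTHS, rng=rng)
        with pytest.raises(ShapeError, match="divisible by 16"):
            encoder_forward(enc, rng.normal(size=(3, 30, 32)))

    def test_eval_mode_deterministic(self, rng):
        enc = Encoder(widths=WIDTHS, rng=rng).eval()
        x = rng.normal(size=(3, 32, 32)).astype(np.float32)
        a = encoder_forward(enc, x).bottleneck.numpy()
        b = encoder_forward(enc, x).bottleneck.numpy()
        np.testing.assert_array_equal(a, b)


class TestDecoder:
    def test_output_channels_and_resolution(self, rng):
        enc = Encoder(widths=WIDTHS, rng=rng)
        dec = Decoder(widths=WIDTHS, n_classes=8, rng=rng)
        out = encoder_forward(enc, rng.normal(size=(3, 32, 32)).astype(np.float32))
        logits = decoder_forward(dec, out)
        assert logits.shape == (1, 9, 32, 32)

    def test_binary_configuration(self, rng):
        enc = Encoder(widths=WIDTHS, rng=rng)
        dec = Decoder(widths=WIDTHS, n_classes=1, rng=rng)
        out = encoder_forward(enc, rng.normal(size=(3, 32, 32)).astype(np.float32))
        assert decoder_forward(dec, out).shape[1] == 2

    def test_zero_input_gives_spatially_constant_bias_field(self, rng):
        dec = Decoder(widths=WIDTHS, n_classes=3, rng=rng).eval()
        enc = EncoderOutput(
            bottleneck=Tensor(np.zeros((1, 64, 2, 2), dtype=np.float32)),
            skips=[Tensor(np.zeros((1, 8, 16, 16), dtype=np.float32)),
                   Tensor(np.zeros((1, 16, 8, 8), dtype=np.float32)),
                   Tensor(np.zeros((1, 32, 4, 4), dtype=np.float32))],
        )
        logits = decoder_forward(dec, enc).numpy()
        for c in range(logits.shape[1]):
            assert np.ptp(logits[0, c]) == pytest.approx(0.0, abs=1e-5)

    def test_mismatched_skip_rejected(self, rng):
        dec = Decoder(widths=WIDTHS, n_classes=3, rng=rng)
        enc = EncoderOutput(
            bottleneck=Tensor(np.zeros((1, 64, 2, 2), dtype=np.float32)),
            skips=[Tensor(np.zeros((1, 8, 16, 16), dtype=np.float32)),
                   Tensor(np.zeros((1, 16, 8, 8), dtype=np.float32)),
                   Tensor(np.zeros((1, 32, 6, 6), dtype=np.float32))],
        )
        with pytest.raises(ShapeError, match="skip"):
            decoder_forward(dec, enc)


class TestRFEUNet:
    def test_end_to_end_shape(self, tiny_net, rng):
        logits = rfe_unet_forward(tiny_net, rng.normal(size=(3, 32, 32)).astype(np.float32))
        assert logits.shape == (9, 32, 32)

    def test_zero_rfe_layers_is_plain_unet(self, rng):
        net = RFEUNet(resolution=48, widths=WIDTHS, rfe_layers=0, units_per_stage=1, seed=1)
        logits = rfe_unet_forward(net, rng.normal(size=(3, 48, 48)).astype(np.float32))
        assert logits.shape == (9, 48, 48)
        assert not any(name.startswith("rfe") for name, _ in net.named_parameters())

    def test_argmax_labels_in_range(self, tiny_net, rng):
        logits = rfe_unet_forward(tiny_net, rng.normal(size=(3, 32, 32)).astype(np.float32))
        labels = logits.argmax(axis=0)
        assert labels.min() >= 0 and labels.max() <= 8

    def test_rfe_depth_changes_only_bottleneck_parameters(self):
        net1 = RFEUNet(resolution=32, widths=WIDTHS, rfe_layers=1, units_per_stage=1, seed=0)
        net2 = RFEUNet(resolution=32, widths=WIDTHS, rfe_layers=2, units_per_stage=1, seed=0)
        names1 = {n for n, _ in net1.named_parameters()}
        names2 = {n for n, _ in net2.named_parameters()}
        extra = names2 - names1
        assert extra and all(n.startswith("rfe.") for n in extra)
        enc_dec = lambda net: sum(p.size for n, p in net.named_parameters()
                                  if not n.startswith("rfe."))
        assert enc_dec(net1) == enc_dec(net2)

    def test_odd_resolution_rejected(self):
        with pytest.raises(ShapeError, match="divisible by 32"):
            RFEUNet(resolution=48, widths=WIDTHS, rfe_layers=1)

    def test_single_training_step_decreases_loss(self, rng):
        net = RFEUNet(resolution=32, widths=(4, 8, 12, 16), rfe_layers=1,
                      units_per_stage=1, seed=3)
        x = Tensor(rng.normal(size=(2, 3, 32, 32)).astype(np.float32))
        y = rng.integers(0, 9, (2, 32, 32))
        opt = SGD(net.parameters(), lr=0.01, momentum=0.9, weight_decay=1e-4)
        before = mixed_loss_graph(net(x), y, LossWeights()).item()
        loss = mixed_loss_graph(net(x), y, LossWeights())
        opt.zero_grad()
        loss.backward()
        opt.step()
        after = mixed_loss_graph(net(x), y, LossWeights()).item()
        assert after < before
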