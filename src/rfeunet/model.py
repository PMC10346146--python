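"""RFE-UNet: residual convolutional encoder, RFE bottleneck, skip-connected decoder.

The encoder is a compact residual network: a stride-2 stem followed by three
residual stages, each halving resolution and doubling width, so a
3 x 224 x 224 image maps to a 512 x 14 x 14 bottleneck with the default
widths (64, 128, 256, 512).  The three pre-bottleneck stage outputs feed the
decoder as skip connections at 1/2, 1/4 and 1/8 resolution.  The decoder
upsamples bilinearly (2x) and convolves, concatenating the matching skip at
the first three stages, and a final 1x1 convolution emits one logit channel
per class plus background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .nn import BatchNorm2d, Conv2d, Module, ModuleList, Sequential, Tensor, cat, resize_bilinear
from .rfe import RFELayer

__all__ = [
    "ShapeError",
    "EncoderOutput",
    "Encoder",
    "Decoder",
    "RFEUNet",
    "encoder_forward",
    "decoder_forward",
    "rfe_unet_forward",
]


class ShapeError(ValueError):
    """Raised when an input does not satisfy the network's divisibility contract."""


@dataclass
class EncoderOutput:
    bottleneck: Tensor           # (N, widths[3], H/16, W/16)
    skips: List[Tensor]          # [1/2, 1/4, 1/8] resolution, widths[0..2]


class _ReLU(Module):
    def forward(self, x):
        return x.relu()


class ResidualUnit(Module):
    def __init__(self, cin, cout, stride=1, rng=None, dtype=np.float32):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, padding=1, bias=False, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(cout, dtype=dtype)
        self.conv2 = Conv2d(cout, cout, 3, stride=1, padding=1, bias=False, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        if stride != 1 or cin != cout:
            self.proj = Sequential(
                Conv2d(cin, cout, 1, stride=stride, padding=0, bias=False, rng=rng, dtype=dtype),
                BatchNorm2d(cout, dtype=dtype),
            )
        else:
            self.proj = None

    def forward(self, x):
        shortcut = self.proj(x) if self.proj is not None else x
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        return (y + shortcut).relu()


class Encoder(Module):
    """Stem + three residual stages; returns bottleneck and three skips."""

    def __init__(self, widths: Sequence[int] = (64, 128, 256, 512), units_per_stage: int = 2,
                 in_channels: int = 3, rng=None, dtype=np.float32):
        super().__init__()
        if len(widths) != 4:
            raise ValueError("encoder expects four stage widths")
        self.widths = tuple(widths)
        w0, w1, w2, w3 = widths
        self.stem = Sequential(
            Conv2d(in_channels, w0, 3, stride=2, padding=1, bias=False, rng=rng, dtype=dtype),
            BatchNorm2d(w0, dtype=dtype),
            _ReLU(),
        )
        def stage(cin, cout):
            units = [ResidualUnit(cin, cout, stride=2, rng=rng, dtype=dtype)]
            units += [ResidualUnit(cout, cout, rng=rng, dtype=dtype) for _ in range(units_per_stage - 1)]
            return Sequential(*units)
        self.stage1 = stage(w0, w1)
        self.stage2 = stage(w1, w2)
        self.stage3 = stage(w2, w3)

    def forward(self, x: Tensor) -> EncoderOutput:
        _, _, height, width = x.shape
        if height % 16 or width % 16:
            raise ShapeError(
                f"input spatial dims ({height}, {width}) must be divisible by 16"
            )
        s1 = self.stem(x)      # 1/2, w0
        s2 = self.stage1(s1)   # 1/4, w1
        s3 = self.stage2(s2)   # 1/8, w2
        b = self.stage3(s3)    # 1/16, w3
        return EncoderOutput(bottleneck=b, skips=[s1, s2, s3])


class _UpBlock(Module):
    """2x bilinear upsample, optional skip concatenation, 3x3 conv + BN + ReLU."""

    def __init__(self, cin, cout, rng=None, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(cin, cout, 3, stride=1, padding=1, bias=False, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(cout, dtype=dtype)

    def forward(self, x, skip=None):
        _, _, h, w = x.shape
        x = resize_bilinear(x, 2 * h, 2 * w)
        if skip is not None:
            if skip.shape[2:] != x.shape[2:]:
                raise ShapeError(
                    f"skip spatial shape {skip.shape[2:]} does not match "
                    f"upsampled shape {x.shape[2:]}"
                )
            x = cat([x, skip], axis=1)
        return self.bn(self.conv(x)).relu()


class Decoder(Module):
    """Four upsampling stages; skips fused at the first three; 1x1 head."""

    def __init__(self, widths: Sequence[int] = (64, 128, 256, 512), n_classes: int = 8,
                 rng=None, dtype=np.float32):
        super().__init__()
        w0, w1, w2, w3 = widths
        self.n_classes = n_classes
        self.up1 = _UpBlock(w3 + w2, w2, rng=rng, dtype=dtype)
        self.up2 = _UpBlock(w2 + w1, w1, rng=rng, dtype=dtype)
        self.up3 = _UpBlock(w1 + w0, w0, rng=rng, dtype=dtype)
        self.up4 = _UpBlock(w0, w0, rng=rng, dtype=dtype)
        self.head = Conv2d(w0, n_classes + 1, 1, rng=rng, dtype=dtype)

    def forward(self, enc: EncoderOutput) -> Tensor:
        s1, s2, s3 = enc.skips
        x = self.up1(enc.bottleneck, s3)
        x = self.up2(x, s2)
        x = self.up3(x, s1)
        x = self.up4(x)
        return self.head(x)


class RFEUNet(Module):
    """Encoder -> stacked RFE layers on the bottleneck -> decoder.

    With ``rfe_layers=0`` the model reduces to a plain residual U-shaped
    network (the ablation baseline).  The RFE correlation matrices are sized
    at construction from ``resolution``, so the bottleneck (resolution / 16)
    must be even — i.e. resolution divisible by 32 — whenever RFE layers are
    stacked.
    """

    def __init__(self, resolution: int = 224, n_classes: int = 8,
                 widths: Sequence[int] = (64, 128, 256, 512), rfe_layers: int = 2,
                 units_per_stage: int = 2, rfe_hidden_mult: int = 4,
                 rfe_weight_sigma: float = 0.02, seed=None, rng=None, dtype=np.float32):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(seed)
        if resolution % 16:
            raise ShapeError("resolution must be divisible by 16")
        if rfe_layers > 0 and (resolution // 16) % 2:
            raise ShapeError("resolution must be divisible by 32 when RFE layers are used")
        self.config = {
            "resolution": resolution, "n_classes": n_classes, "widths": tuple(widths),
            "rfe_layers": rfe_layers, "units_per_stage": units_per_stage,
            "rfe_hidden_mult": rfe_hidden_mult, "rfe_weight_sigma": rfe_weight_sigma,
        }
        self.encoder = Encoder(widths, units_per_stage=units_per_stage, rng=rng, dtype=dtype)
        block = resolution // 32
        self.rfe = ModuleList([
            RFELayer(block, block, rng=rng, weight_sigma=rfe_weight_sigma,
                     hidden_mult=rfe_hidden_mult, dtype=dtype)
            for _ in range(rfe_layers)
        ])
        self.decoder = Decoder(widths, n_classes=n_classes, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        enc = self.encoder(x)
        b = enc.bottleneck
        for layer in self.rfe:
            b = layer(b)
        return self.decoder(EncoderOutput(bottleneck=b, skips=enc.skips))


# ----------------------------------------------------------- thin functional API
def _as_batched_tensor(image) -> tuple:
    if isinstance(image, Tensor):
        arr = image.data
    else:
        arr = np.asarray(image)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    return Tensor(arr), squeeze


def encoder_forward(encoder: Encoder, image) -> EncoderOutput:
    """Run the encoder on a (3, H, W) or (N, 3, H, W) image."""
    x, _ = _as_batched_tensor(image)
    return encoder(x)


def decoder_forward(decoder: Decoder, enc: EncoderOutput) -> Tensor:
    return decoder(enc)


def rfe_unet_forward(model: RFEUNet, image) -> np.ndarray:
    """Full forward pass; returns logits as an ndarray, unbatched if the
    input was a single (3, H, W) image."""
    x, squeeze = _as_batched_tensor(image)
    logits = model(x).numpy()
    return logits[0] if squeeze else logits
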