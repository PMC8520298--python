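"""The four building blocks of the multi-scale attention U-Net.

* :class:`MSRB` — multi-scale residual block. Two parallel branches (one
  3x3 conv; two serial 3x3 convs emulating a 5x5 receptive field at
  18C^2 instead of 25C^2 weights), concatenated, fused by a 1x1 conv,
  plus a 1x1-projected residual of the input, with DropBlock applied
  last.
* :class:`MSAM` — multi-scale attention module. A pooling pyramid at
  scales 2/4/8 fused coarse-to-fine by bilinear upsampling and 3x3
  convs; a final 1x1 conv and sigmoid give a full-resolution attention
  map in (0,1) that rescales the input elementwise.
* :class:`AASPP` — attention atrous spatial pyramid pooling: four
  parallel branches (1x1, and 3x3 dilated at rates 2/4/8), each gated by
  an MSAM, concatenated and fused by a 1x1 conv.
* :class:`RASM` — residual attention skip module: upsampled decoder
  features are concatenated with the encoder skip, refined by two MSRBs
  and an MSAM, and summed with 1x1-projected residuals of both inputs.

Every convolution is followed by batch normalization and ReLU, except
the attention-producing 1x1 conv in MSAM which feeds the sigmoid
directly. All blocks preserve spatial dimensions.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor, concat, max_pool2d, resize_bilinear
from .nn import ConvBNReLU, Conv2d, DropBlock2d, Module

__all__ = ["BlockConfig", "MSRB", "MSAM", "AASPP", "RASM",
           "check_feature_map", "check_divisible"]


class BlockConfig:
    """Shared block hyperparameters (DropBlock rate and block size)."""

    def __init__(self, dropblock_rate: float = 0.1, dropblock_size: int = 7):
        if not 0.0 <= dropblock_rate <= 1.0:
            raise ValueError("dropblock_rate must be in [0, 1]")
        if dropblock_size < 1:
            raise ValueError("dropblock_size must be >= 1")
        self.dropblock_rate = dropblock_rate
        self.dropblock_size = dropblock_size


def check_feature_map(x, name: str = "input") -> Tensor:
    """Validate an NHWC feature map: rank 4, finite entries."""
    t = as_tensor(x)
    if t.ndim != 4:
        raise ValueError(f"{name} must be rank-4 (batch, height, width, channels), got shape {t.shape}")
    if not np.all(np.isfinite(t.data)):
        raise ValueError(f"{name} contains non-finite values")
    return t


def check_divisible(x: Tensor, k: int, name: str = "input"):
    _, h, w, _ = x.shape
    if h % k:
        raise ValueError(f"{name} height {h} is not divisible by {k}")
    if w % k:
        raise ValueError(f"{name} width {w} is not divisible by {k}")


class MSRB(Module):
    """Multi-scale residual block: C_in -> C_out, spatial dims preserved."""

    def __init__(self, in_channels: int, out_channels: int,
                 cfg: BlockConfig | None = None, *, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        cfg = cfg or BlockConfig()
        # branches run at the output width (the block replaces the plain
        # double conv, whose layers are in->out, out->out)
        self.branch_a = ConvBNReLU(in_channels, out_channels, 3, rng=rng, dtype=dtype)
        self.branch_b1 = ConvBNReLU(in_channels, out_channels, 3, rng=rng, dtype=dtype)
        self.branch_b2 = ConvBNReLU(out_channels, out_channels, 3, rng=rng, dtype=dtype)
        self.fuse = ConvBNReLU(2 * out_channels, out_channels, 1, rng=rng, dtype=dtype)
        self.residual = ConvBNReLU(in_channels, out_channels, 1, rng=rng, dtype=dtype)
        self.dropblock = DropBlock2d(cfg.dropblock_rate, cfg.dropblock_size, rng=rng)

    def forward(self, x):
        x = check_feature_map(x)
        a = self.branch_a(x)
        b = self.branch_b2(self.branch_b1(x))
        fused = self.fuse(concat([a, b]))
        out = fused + self.residual(x)
        return self.dropblock(out)


class MSAM(Module):
    """Multi-scale attention module: output shape equals input shape.

    Requires spatial dimensions divisible by 8 (the deepest pooling
    scale); violating inputs are rejected rather than silently padded.
    """

    def __init__(self, channels: int, *, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.conv_p8 = ConvBNReLU(channels, channels, 3, rng=rng, dtype=dtype)
        self.conv_p4 = ConvBNReLU(channels, channels, 3, rng=rng, dtype=dtype)
        self.conv_p2 = ConvBNReLU(channels, channels, 3, rng=rng, dtype=dtype)
        self.conv_out = Conv2d(channels, channels, 1, rng=rng, dtype=dtype)

    def attention(self, x) -> Tensor:
        """The sigmoid attention map, same shape as ``x``."""
        x = check_feature_map(x)
        check_divisible(x, 8)
        _, h, w, _ = x.shape
        p2 = max_pool2d(x, 2)
        p4 = max_pool2d(x, 4)
        p8 = max_pool2d(x, 8)
        # coarse-to-fine fusion: upsample, conv, add
        p4f = p4 + self.conv_p8(resize_bilinear(p8, h // 4, w // 4))
        p2f = p2 + self.conv_p4(resize_bilinear(p4f, h // 2, w // 2))
        up = resize_bilinear(self.conv_p2(p2f), h, w)
        return self.conv_out(up).sigmoid()

    def forward(self, x):
        x = as_tensor(x)
        return x * self.attention(x)


class AASPP(Module):
    """Attention atrous spatial pyramid pooling: C_in -> C_out."""

    RATES = (1, 2, 4, 8)

    def __init__(self, in_channels: int, out_channels: int, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        self.branches = [
            ConvBNReLU(in_channels, out_channels, 1 if r == 1 else 3,
                       dilation=r, rng=rng, dtype=dtype)
            for r in self.RATES
        ]
        self.attentions = [MSAM(out_channels, rng=rng, dtype=dtype)
                           for _ in self.RATES]
        self.fuse = ConvBNReLU(4 * out_channels, out_channels, 1, rng=rng,
                               dtype=dtype)

    def forward(self, x):
        x = check_feature_map(x)
        check_divisible(x, 8)
        feats = [att(branch(x))
                 for branch, att in zip(self.branches, self.attentions)]
        return self.fuse(concat(feats))


class RASM(Module):
    """Residual attention skip module.

    Fuses an encoder skip (``low``, shape (B, H, W, C_low)) with decoder
    features at half resolution (``high``, shape (B, H/2, W/2, C_high))
    into (B, H, W, C_out): two 1x1 residual projections plus an
    MSRB-MSRB-MSAM refinement of the concatenated pair.
    """

    def __init__(self, low_channels: int, high_channels: int,
                 out_channels: int, cfg: BlockConfig | None = None, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        cfg = cfg or BlockConfig()
        self.proj_low = ConvBNReLU(low_channels, out_channels, 1, rng=rng, dtype=dtype)
        self.proj_high = ConvBNReLU(high_channels, out_channels, 1, rng=rng, dtype=dtype)
        self.msrb1 = MSRB(low_channels + high_channels, out_channels, cfg,
                          rng=rng, dtype=dtype)
        self.msrb2 = MSRB(out_channels, out_channels, cfg, rng=rng, dtype=dtype)
        self.attention = MSAM(out_channels, rng=rng, dtype=dtype)

    def forward(self, low, high):
        low = check_feature_map(low, "low")
        high = check_feature_map(high, "high")
        _, h, w, _ = low.shape
        _, hh, hw, _ = high.shape
        if (hh, hw) != (h // 2, w // 2) or h % 2 or w % 2:
            raise ValueError(
                f"high spatial dims {(hh, hw)} must be exactly half of low {(h, w)}"
            )
        check_divisible(low, 8, "low")
        up = resize_bilinear(high, h, w)
        main = self.attention(self.msrb2(self.msrb1(concat([up, low]))))
        return self.proj_low(low) + self.proj_high(up) + main
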