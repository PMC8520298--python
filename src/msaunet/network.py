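"""The multi-scale attention U-Net and its ablation variants.

Architecture (full configuration): an encoder of ``depth`` stages, each
an :class:`~msaunet.blocks.MSRB` followed by 2x2 max pooling with
filters doubling per stage; an :class:`~msaunet.blocks.AASPP` context
bridge at the deepest resolution (output width equal to the deepest
encoder width); a decoder of ``depth`` :class:`~msaunet.blocks.RASM`
stages, each consuming the matching encoder feature map as the
low-level input and halving the channel width; and a 1x1 conv + sigmoid
head producing a single-channel foreground probability map.

Ablation switches recover a vanilla U-Net: ``use_msrb=False`` replaces
MSRB with a plain double 3x3 conv block, ``use_aaspp=False`` replaces
the bridge with identity, ``use_rasm=False`` replaces the skip fusion
with bilinear-upsample + concat + double conv.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Tensor, concat, max_pool2d, no_grad, resize_bilinear
from .blocks import AASPP, BlockConfig, MSRB, RASM, check_feature_map
from .nn import Conv2d, ConvBNReLU, Module

__all__ = ["ModelConfig", "MSAUNet", "build_model", "predict",
           "count_parameters", "save_model", "load_model"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by ``2**depth``; when the attention
    modules are enabled the deepest resolution reached by their pooling
    pyramids must additionally be divisible by 8 (see
    :meth:`validate`).
    """

    depth: int = 4
    base_filters: int = 64
    input_size: tuple = (512, 512)
    in_channels: int = 1
    use_msrb: bool = True
    use_aaspp: bool = True
    use_rasm: bool = True
    dropblock_rate: float = 0.1
    dropblock_size: int = 7
    seed: int = 0
    dtype: str = "float32"

    def validate(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        h, w = self.input_size
        req = 2 ** self.depth
        if self.use_aaspp:
            req = max(req, 8 * 2 ** self.depth)
        elif self.use_rasm:
            req = max(req, 8 * 2 ** (self.depth - 1))
        if h % req or w % req:
            raise ValueError(
                f"input_size {self.input_size} incompatible with depth "
                f"{self.depth} and enabled blocks: both dimensions must be "
                f"divisible by {req} (minimum compatible size {req}x{req})"
            )

    def stage_filters(self) -> list:
        return [self.base_filters * 2 ** i for i in range(self.depth)]


class PlainDoubleConv(Module):
    """Vanilla U-Net stage: two 3x3 conv+BN+ReLU layers."""

    def __init__(self, in_channels, out_channels, *, rng, dtype):
        super().__init__()
        self.conv1 = ConvBNReLU(in_channels, out_channels, 3, rng=rng, dtype=dtype)
        self.conv2 = ConvBNReLU(out_channels, out_channels, 3, rng=rng, dtype=dtype)

    def forward(self, x):
        return self.conv2(self.conv1(x))


class PlainSkipFusion(Module):
    """Vanilla U-Net decoder stage: upsample, concat skip, double conv."""

    def __init__(self, low_channels, high_channels, out_channels, *, rng, dtype):
        super().__init__()
        self.block = PlainDoubleConv(low_channels + high_channels,
                                     out_channels, rng=rng, dtype=dtype)

    def forward(self, low, high):
        _, h, w, _ = low.shape
        up = resize_bilinear(high, h, w)
        return self.block(concat([up, low]))


class MSAUNet(Module):
    """Encoder--bridge--decoder segmentation network (NHWC)."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        bcfg = BlockConfig(config.dropblock_rate, config.dropblock_size)
        filters = config.stage_filters()

        self.encoder = []
        c_in = config.in_channels
        for c_out in filters:
            if config.use_msrb:
                stage = MSRB(c_in, c_out, bcfg, rng=rng, dtype=dtype)
            else:
                stage = PlainDoubleConv(c_in, c_out, rng=rng, dtype=dtype)
            self.encoder.append(stage)
            c_in = c_out

        c_deep = filters[-1]
        self.bridge = (AASPP(c_deep, c_deep, rng=rng, dtype=dtype)
                       if config.use_aaspp else None)

        self.decoder = []
        c_high = c_deep
        for c_skip in reversed(filters):
            if config.use_rasm:
                stage = RASM(c_skip, c_high, c_skip, bcfg, rng=rng, dtype=dtype)
            else:
                stage = PlainSkipFusion(c_skip, c_high, c_skip, rng=rng, dtype=dtype)
            self.decoder.append(stage)
            c_high = c_skip

        self.head = Conv2d(filters[0], 1, 1, rng=rng, dtype=dtype)

    # ------------------------------------------------------------------
    def forward(self, x) -> Tensor:
        x = check_feature_map(x)
        _, h, w, c = x.shape
        eh, ew = self.config.input_size
        if (h, w) != (eh, ew) or c != self.config.in_channels:
            raise ValueError(
                f"input shape {(h, w, c)} does not match configured "
                f"{(eh, ew, self.config.in_channels)}"
            )
        skips = []
        for stage in self.encoder:
            x = stage(x)
            skips.append(x)
            x = max_pool2d(x, 2)
        if self.bridge is not None:
            x = self.bridge(x)
        for stage, skip in zip(self.decoder, reversed(skips)):
            x = stage(skip, x)
        return self.head(x).sigmoid()

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass returning probabilities in (0,1)."""
        was_training = self.training
        self.eval()
        try:
            arr = np.asarray(batch, dtype=np.dtype(self.config.dtype))
            if arr.ndim == 3:
                arr = arr[..., None]
            with no_grad():
                out = self.forward(Tensor(arr)).data
        finally:
            if was_training:
                self.train()
        eps = 1e-6  # keep probabilities strictly inside (0, 1)
        return np.clip(out, eps, 1.0 - eps)


def build_model(config: ModelConfig) -> MSAUNet:
    return MSAUNet(config)


def predict(model: MSAUNet, batch: np.ndarray) -> np.ndarray:
    return model.predict(batch)


def count_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def save_model(model: MSAUNet, path):
    """Write a single-file checkpoint: config JSON + weight arrays."""
    state = model.state_dict()
    meta = {"checkpoint_version": CHECKPOINT_VERSION,
            "config": asdict(model.config)}
    np.savez_compressed(path, __meta__=json.dumps(meta), **state)


def load_model(path) -> MSAUNet:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        version = meta.get("checkpoint_version")
        if version != CHECKPOINT_VERSION:
            raise ValueError(
                f"incompatible checkpoint version {version} "
                f"(expected {CHECKPOINT_VERSION})"
            )
        cfg_dict = meta["config"]
        cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
        config = ModelConfig(**cfg_dict)
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    model = MSAUNet(config)
    model.load_state_dict(state)
    return model
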