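"""Layers, parameter containers, and the Adam optimizer.

A :class:`Module` owns :class:`Parameter` leaves and child modules,
mirroring the familiar layer-object pattern of mainstream deep-learning
toolkits; ``state_dict``/``load_state_dict`` give flat name->array views
used by the checkpoint format.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import maximum_filter

from .autograd import Tensor, batch_norm, conv2d

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ConvBNReLU",
    "DropBlock2d",
    "Adam",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class: tracks parameters, buffers and submodules by attribute."""

    def __init__(self):
        self.training = True

    # -- containment ---------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        buffers = getattr(self, "_buffer_names", ())
        for name in buffers:
            yield prefix + name, getattr(self, name)
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    # -- modes ---------------------------------------------------------
    def train(self):
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ---------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(
                f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(p.data.dtype).copy()
        for name, b in bufs.items():
            b[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Same-padded NHWC convolution with He fan-in normal initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, *, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        k = kernel_size
        fan_in = k * k * in_channels
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(k, k, in_channels, out_channels)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))
        self.dilation = dilation
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return batch_norm(x, self.gamma, self.beta, self.running_mean,
                          self.running_var, self.training,
                          momentum=self.momentum, eps=self.eps)


class ConvBNReLU(Module):
    """conv -> batch-norm -> ReLU; the activation can be disabled."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, relu: bool = True, *,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size,
                           dilation=dilation, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_channels, dtype=dtype)
        self.relu = relu

    def forward(self, x):
        out = self.bn(self.conv(x))
        return out.relu() if self.relu else out


class DropBlock2d(Module):
    """Structured dropout: zeroes contiguous ``block_size`` squares.

    Seed positions are Bernoulli-sampled in the valid interior at a rate
    chosen so the expected fraction of dropped activations equals
    ``rate``; the surviving activations are rescaled to preserve the
    expected sum. The mask is shared across channels. Identity in
    inference mode or at rate 0.
    """

    def __init__(self, rate: float = 0.1, block_size: int = 7, *,
                 rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate <= 1.0:
            raise ValueError("dropblock rate must be in [0, 1]")
        if block_size < 1:
            raise ValueError("dropblock block size must be >= 1")
        self.rate = rate
        self.block_size = block_size
        self.rng = rng

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            return x
        b_, h, w, _ = x.shape
        bs = min(self.block_size, h, w)
        valid_h = h - bs + 1
        valid_w = w - bs + 1
        gamma = (self.rate / (bs * bs)) * (h * w) / (valid_h * valid_w)
        seeds = np.zeros((b_, h, w), dtype=bool)
        seeds[:, (bs - 1) // 2:(bs - 1) // 2 + valid_h,
              (bs - 1) // 2:(bs - 1) // 2 + valid_w] = (
            self.rng.random((b_, valid_h, valid_w)) < gamma
        )
        block = maximum_filter(seeds.astype(np.uint8), size=(1, bs, bs)) > 0
        keep = (~block).astype(x.data.dtype)
        denom = keep.sum()
        if denom == 0:  # everything dropped: degenerate draw, output zero
            scale = 0.0
        else:
            scale = keep.size / denom
        mask = Tensor(keep[..., None] * scale)
        return x * mask


class Adam:
    """Adam optimizer (first/second-moment estimates, bias-corrected)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-7):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
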