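"""Neural-network layers built on the autodiff core.

Follows the usual Module idiom: layers own :class:`Parameter` leaves,
``parameters()`` walks the tree, ``train()``/``eval()`` toggle behaviour of
batch-norm and dropout, and ``state_dict``/``load_state_dict`` serialise to
plain NumPy arrays.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "BatchNorm2d",
    "LayerNorm",
    "ReLU",
    "Dropout",
    "MaxPool2d",
    "Sequential",
    "MultiheadSelfAttention",
    "TransformerEncoderLayer",
    "xavier_uniform",
    "kaiming_uniform",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def xavier_uniform(shape, rng: np.random.Generator, dtype=np.float32) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    if len(shape) > 2:
        receptive = int(np.prod(shape[2:]))
        fan_in, fan_out = shape[1] * receptive, shape[0] * receptive
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def kaiming_uniform(shape, rng: np.random.Generator, dtype=np.float32) -> np.ndarray:
    fan_in = shape[1] * int(np.prod(shape[2:])) if len(shape) > 2 else shape[-2]
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Module:
    def __init__(self):
        self.training = True

    # tree walking ----------------------------------------------------------

    def named_children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self.named_children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self.named_children():
            yield from child.modules()

    # mode ------------------------------------------------------------------

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    # (de)serialisation -----------------------------------------------------

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, "Module", str]]:
        for key in self._buffers():
            yield prefix + key, self, key
        for name, child in self.named_children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for full, owner, key in self.named_buffers():
            state[full] = getattr(owner, key).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        for name, arr in state.items():
            if name in own:
                own[name].data = np.asarray(arr, dtype=own[name].data.dtype).copy()
        for full, owner, key in self.named_buffers():
            if full in state:
                setattr(owner, key, np.asarray(state[full], dtype=np.float64).copy())

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init: str = "kaiming", dtype=np.float32):
        super().__init__()
        initf = xavier_uniform if init == "xavier" else kaiming_uniform
        self.weight = Parameter(initf((in_features, out_features), rng, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride, self.padding = stride, padding
        self.weight = Parameter(kaiming_uniform((out_ch, in_ch, kernel, kernel), rng, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def named_parameters(self, prefix: str = ""):
        yield prefix + "weight", self.weight
        if self.bias is not None:
            yield prefix + "bias", self.bias

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(num_features, dtype=dtype))
        self.bias = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ad.batchnorm(x, self.weight, self.bias, self.eps)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            return out
        return ad.batchnorm_eval(
            x, self.weight, self.bias,
            self.running_mean.astype(x.dtype), self.running_var.astype(x.dtype), self.eps,
        )


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=dtype))
        self.bias = Parameter(np.zeros(dim, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ad.layernorm(x, self.weight, self.bias, self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Dropout(Module):
    """Inverted dropout; the mask stream comes from the Generator handed in."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        return ad.dropout(x, self.p, self.rng)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.maxpool2d(x, self.kernel, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention with h heads over (B, S, D)."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if dim % heads:
            raise ValueError(f"model dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.head_dim = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim, rng, init="xavier", dtype=dtype)
        self.proj = Linear(dim, dim, rng, init="xavier", dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        B, S, D = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(x)  # (B, S, 3D)
        qkv = qkv.reshape(B, S, 3, h, hd).transpose(2, 0, 3, 1, 4)  # (3, B, h, S, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = q.matmul(k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(hd))
        att = ad.softmax(att, axis=-1)
        out = att.matmul(v)  # (B, h, S, hd)
        out = out.transpose(0, 2, 1, 3).reshape(B, S, D)
        return self.proj(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: attention + FFN, residual connections,
    dropout applied to each sublayer output."""

    def __init__(self, dim: int, heads: int, ffn_dim: int, dropout_p: float,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.attn = MultiheadSelfAttention(dim, heads, rng, dtype)
        self.norm1 = LayerNorm(dim, dtype=dtype)
        self.ff1 = Linear(dim, ffn_dim, rng, init="xavier", dtype=dtype)
        self.ff2 = Linear(ffn_dim, dim, rng, init="xavier", dtype=dtype)
        self.norm2 = LayerNorm(dim, dtype=dtype)
        self.drop = Dropout(dropout_p, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.drop(self.attn(x)))
        x = self.norm2(x + self.drop(self.ff2(self.ff1(x).relu())))
        return x
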