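"""Neural-network building blocks on top of the autodiff tensor engine.

Conventions: convolutional layers take (batch, channels, length) arrays,
attention/transformer layers take (batch, tokens, channels).  Every layer
draws its initial weights from an explicitly passed numpy Generator so that
model construction is reproducible.
"""

from __future__ import annotations

import hashlib
from collections import OrderedDict
from typing import Iterator

import numpy as np

from .tensor import Tensor, concatenate, conv1d, softmax


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- persistence ----------------------------------------------------------

    def _named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and not value.requires_grad:
                yield prefix + name, value.data
        for name, child in self._children():
            yield from child._named_buffers(prefix + name + ".")

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        state: OrderedDict[str, np.ndarray] = OrderedDict()
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for name, b in self._named_buffers():
            state[name] = b.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        own.update(dict(self._named_buffers()))
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, arr in state.items():
            target = own[name]
            if isinstance(target, Tensor):
                target.data[...] = arr
            else:  # buffer: own[name] is the ndarray itself
                target[...] = arr

    def weight_hash(self) -> str:
        """SHA-256 over all parameters and buffers, in name order."""
        h = hashlib.sha256()
        for name, arr in sorted(self.state_dict().items()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


def _param(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = float(np.sqrt(1.0 / fan_in))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = _param(rng, (in_features, out_features), in_features)
        self.bias = _param(rng, (out_features,), in_features) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | str = 0, groups: int = 1, bias: bool = True):
        super().__init__()
        if padding == "same":
            if stride != 1 or kernel_size % 2 == 0:
                raise ValueError("'same' padding needs stride 1 and odd kernel")
            padding = kernel_size // 2
        self.stride = stride
        self.padding = int(padding)
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size
        self.weight = _param(
            rng, (out_channels, in_channels // groups, kernel_size), fan_in)
        self.bias = _param(rng, (out_channels,), fan_in) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class BatchNorm1d(Module):
    """Batch normalization over (batch, time) for (B, C, L) inputs."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = Tensor(np.zeros(num_features))
        self.running_var = Tensor(np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import fused_norm
        if self.training:
            mean = x.data.mean(axis=(0, 2), keepdims=True)
            var = x.data.var(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean.data[...] = (
                (1 - m) * self.running_mean.data + m * mean.ravel())
            self.running_var.data[...] = (
                (1 - m) * self.running_var.data + m * var.ravel())
            stats, from_x = (mean, var), True
        else:
            stats = (self.running_mean.data.reshape(1, -1, 1),
                     self.running_var.data.reshape(1, -1, 1))
            from_x = False
        return fused_norm(x, self.gamma, self.beta, axes=(0, 2),
                          eps=self.eps, param_shape=(1, -1, 1),
                          stats=stats, stats_from_x=from_x)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        from .tensor import fused_norm
        return fused_norm(x, self.gamma, self.beta, axes=(-1,), eps=self.eps)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = float(p)
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class SqueezeExcite(Module):
    """Channel attention: global average pool -> bottleneck MLP -> sigmoid gate.

    Operates on (B, C, L); the gate lies strictly in (0, 1) per channel.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def gate(self, x: Tensor) -> Tensor:
        squeezed = x.mean(axis=2)  # (B, C)
        return self.fc2(self.fc1(squeezed).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        g = self.gate(x)
        return x * g.reshape(g.shape[0], g.shape[1], 1)


class MultiHeadAttention(Module):
    """Scaled dot-product attention, multi-head, with output projection.

    Query, key and value may come from different sources (cross-attention).
    The most recent attention weights are kept on `last_attn` with shape
    (B, heads, T_q, T_k) for inspection.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model {d_model} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.w_q = Linear(d_model, d_model, rng)
        self.w_k = Linear(d_model, d_model, rng)
        self.w_v = Linear(d_model, d_model, rng)
        self.w_o = Linear(d_model, d_model, rng)
        self.drop = Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.last_attn: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def forward(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        b, t_q, d_model = query.shape
        q = self._split(self.w_q(query))
        k = self._split(self.w_k(key))
        v = self._split(self.w_v(value))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_k))
        attn = softmax(scores, axis=-1)
        self.last_attn = attn.data.copy()
        out = attn @ v  # (B, H, T_q, d_k)
        out = out.transpose(0, 2, 1, 3).reshape(b, t_q, d_model)
        return self.drop(self.w_o(out))


class TransformerEncoderLayer(Module):
    """Pre-norm transformer encoder layer: self-attention + position-wise FFN."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 d_ff: int | None = None, dropout: float = 0.1):
        super().__init__()
        d_ff = d_ff or 4 * d_model
        self.attn = MultiHeadAttention(d_model, n_heads, rng, dropout=dropout)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.drop = Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(x)
        x = x + self.attn(h, h, h)
        h = self.norm2(x)
        return x + self.drop(self.ff2(self.ff1(h).relu()))


def sinusoidal_positions(n_tokens: int, d_model: int) -> np.ndarray:
    """Fixed sine/cosine positional encoding, (n_tokens, d_model)."""
    pos = np.arange(n_tokens)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((n_tokens, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


class PositionalEncoding(Module):
    def __init__(self, d_model: int):
        super().__init__()
        self.d_model = d_model

    def forward(self, x: Tensor) -> Tensor:
        _, t, d = x.shape
        return x + Tensor(sinusoidal_positions(t, d)[None])


def global_avg_max_pool(x: Tensor) -> Tensor:
    """Concatenate time-global average and max pooling: (B,T,C) -> (B,2C)."""
    return concatenate([x.mean(axis=1), x.max(axis=1)], axis=1)


def maxpool1d_stride2(x: Tensor) -> Tensor:
    """Max pooling with kernel 2, stride 2 on (B, C, L); L must be even."""
    b, c, length = x.shape
    if length % 2:
        raise ValueError(f"length {length} not divisible by 2")
    return x.reshape(b, c, length // 2, 2).max(axis=3)
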