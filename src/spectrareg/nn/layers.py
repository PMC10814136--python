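"""Neural building blocks: linear/conv layers, LSTM cell, Transformer encoder.

Layers follow the usual convention of holding their parameters as
``Tensor`` leaves; ``Module.parameters()`` walks attributes recursively so
optimizers and state snapshots need no registration boilerplate.
Initialisation mirrors the uniform fan-in scheme common in deep-learning
frameworks, drawn from an explicit ``numpy.random.Generator`` so every
model build is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from ..exceptions import ParameterError
from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "LayerNorm",
    "Dropout",
    "LSTMCell",
    "MultiHeadAttention",
    "TransformerEncoderLayer",
    "positional_encoding",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state snapshots."""

    def __init__(self):
        self.training = True

    def parameters(self):
        params = []
        seen = set()
        stack = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Tensor) and value.requires_grad and id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return params

    def train(self):
        self.training = True
        for m in self._submodules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self._submodules():
            m.training = False
        return self

    def _submodules(self):
        out = []
        stack = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Module):
                    out.append(value)
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    for v in value:
                        if isinstance(v, Module):
                            out.append(v)
                            stack.append(v)
        return out

    def state_dict(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ParameterError("state length does not match parameter count")
        for p, s in zip(params, state):
            p.data = s.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _uniform(rng: np.random.Generator, bound: float, shape) -> Tensor:
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(np.float32), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = _uniform(rng, bound, (in_features, out_features))
        self.bias = _uniform(rng, bound, (out_features,))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim == 2:
            return x @ self.weight + self.bias
        # fold leading axes into one GEMM
        lead = x.shape[:-1]
        flat = x.reshape(int(np.prod(lead)), x.shape[-1])
        out = flat @ self.weight + self.bias
        return out.reshape(*lead, self.weight.shape[1])


class Conv1d(Module):
    """Stride-1 1-D convolution; ``padding='same'`` preserves sequence length."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: str | int = "same", bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.weight = _uniform(rng, bound, (out_channels, in_channels, kernel_size))
        if bias:
            self.bias = _uniform(rng, bound, (out_channels,))
        else:
            self.bias = Tensor(np.zeros(out_channels, dtype=np.float32))
        if padding == "same":
            if kernel_size % 2 == 0:
                raise ParameterError("'same' padding requires an odd kernel size")
            padding = kernel_size // 2
        self.padding = int(padding)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta, self.eps)


class Dropout(Module):
    """Inverted dropout; inert in eval mode so inference is deterministic."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ParameterError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1.0 - self.p)
        return x * mask


class LSTMCell(Module):
    """Single LSTM step; gate layout (input, forget, cell, output)."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        super().__init__()
        bound = 1.0 / np.sqrt(hidden_dim)
        self.w_ih = _uniform(rng, bound, (input_dim, 4 * hidden_dim))
        self.w_hh = _uniform(rng, bound, (hidden_dim, 4 * hidden_dim))
        self.bias = _uniform(rng, bound, (4 * hidden_dim,))
        self.hidden_dim = hidden_dim

    def forward(self, x: Tensor, h: Tensor, c: Tensor):
        gates = x @ self.w_ih + h @ self.w_hh + self.bias
        hd = self.hidden_dim
        i = gates[:, 0 * hd:1 * hd].sigmoid()
        f = gates[:, 1 * hd:2 * hd].sigmoid()
        g = gates[:, 2 * hd:3 * hd].tanh()
        o = gates[:, 3 * hd:4 * hd].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


def positional_encoding(seq_len: int, d_model: int) -> np.ndarray:
    """Sinusoidal position codes.

    ``PE[pos, 2i] = sin(pos / 10000^(2i/d_model))`` and
    ``PE[pos, 2i+1] = cos(pos / 10000^(2i/d_model))``; returned as a
    float64 (seq_len, d_model) array.
    """
    if seq_len < 1 or d_model < 1:
        raise ParameterError("seq_len and d_model must be >= 1")
    if d_model % 2 != 0:
        raise ParameterError("d_model must be even for sin/cos pairing")
    pos = np.arange(seq_len, dtype=np.float64)[:, None]
    i = np.arange(0, d_model, 2, dtype=np.float64)[None, :]
    angle = pos / np.power(10000.0, i / d_model)
    pe = np.empty((seq_len, d_model), dtype=np.float64)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


class MultiHeadAttention(Module):
    """Scaled dot-product attention over ``n_heads`` subspaces.

    Input/output: (N, L, d_model); per-head width d_model / n_heads.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ParameterError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.w_q = Linear(d_model, d_model, rng)
        self.w_k = Linear(d_model, d_model, rng)
        self.w_v = Linear(d_model, d_model, rng)
        self.w_o = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, n: int, length: int) -> Tensor:
        return x.reshape(n, length, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        n, length, _ = x.shape
        q = self._split(self.w_q(x), n, length)
        k = self._split(self.w_k(x), n, length)
        v = self._split(self.w_v(x), n, length)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        att = scores.softmax(axis=-1)
        out = att @ v  # (N, H, L, d_head)
        out = out.transpose(0, 2, 1, 3).reshape(n, length, self.d_model)
        return self.w_o(out)


class TransformerEncoderLayer(Module):
    """Pre-activation-free encoder block: Add&Norm after attention and after
    the position-wise feed-forward (d_model -> ff_hidden -> d_model)."""

    def __init__(self, d_model: int, n_heads: int, ff_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.attention = MultiHeadAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_hidden, rng)
        self.ff2 = Linear(ff_hidden, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attention(x))
        x = self.norm2(x + self.ff2(self.ff1(x).relu()))
        return x
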