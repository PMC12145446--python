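"""Neural-network building blocks (linear, layer norm, attention, LSTM, AdamW)
on top of the :mod:`dilitracer._autograd` engine.

Weight initialization is truncated-normal (|z| <= 2 sd), the conventional
transformer default; every module exposes ``parameters()`` for the optimizer
and ``state_dict()``/``load_state_dict()`` for checkpointing.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Parameter, Tensor, as_tensor, concatenate

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "FeedForward",
    "ViTBlock",
    "TransformerEncoder",
    "BiLSTM",
    "AdamW",
    "trunc_normal",
    "cross_entropy",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated normal: values resampled until within 2 standard deviations."""
    x = rng.standard_normal(shape)
    bad = np.abs(x) > 2.0
    while bad.any():
        x[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(x) > 2.0
    return x * std


class Module:
    """Minimal parameter-container base class."""

    def parameters(self):
        out = []
        for value in vars(self).values():
            if isinstance(value, Parameter):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict key mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != np.asarray(state[k]).shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    """Dense layer with fan-scaled (Glorot) truncated-normal initialization."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        std = float(np.sqrt(2.0 / (d_in + d_out)))
        self.weight = Parameter(trunc_normal(rng, (d_in, d_out), std=std))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = as_tensor(x) @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return as_tensor(x).layer_norm(axis=-1, eps=self.eps) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """k-head self-attention: per-head [q,k,v] = x U_qkv, heads concatenated
    and projected by U_msa. Stores the last attention weights
    (``last_attention``, shape (..., heads, tokens, tokens)) for visualization.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.u_qkv = Linear(dim, 3 * dim, rng, bias=True)
        self.u_msa = Linear(dim, dim, rng, bias=True)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        *batch, n, d = x.shape
        h, dh = self.n_heads, self.head_dim
        qkv = self.u_qkv(x)  # (..., n, 3*d)
        qkv = qkv.reshape(*batch, n, 3, h, dh)
        b = len(batch)
        # axes of qkv: batch[0..b-1], n=b, three=b+1, heads=b+2, dh=b+3
        qkv = qkv.transpose(b + 1, *range(b), b + 2, b, b + 3)  # (3, ..., h, n, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.swapaxes(-1, -2)) * (1.0 / float(np.sqrt(dh)))
        att = att.softmax(axis=-1)
        self.last_attention = att.data.copy()
        out = att @ v  # (..., h, n, dh)
        # back to (..., n, h*dh)
        out = out.transpose(*range(b), b + 1, b, b + 2).reshape(*batch, n, d)
        return self.u_msa(out)


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class ViTBlock(Module):
    """Pre-norm transformer block: x + MSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator, mlp_ratio: float = 4.0, ln_eps: float = 1e-6):
        self.norm1 = LayerNorm(dim, ln_eps)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim, ln_eps)
        self.mlp = FeedForward(dim, int(dim * mlp_ratio), rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.attn(self.norm1(x)) + x
        x = self.mlp(self.norm2(x)) + x
        return x


class TransformerEncoder(Module):
    """L stacked ViT blocks followed by a final layer norm."""

    def __init__(self, dim: int, depth: int, n_heads: int, rng: np.random.Generator, ln_eps: float = 1e-6):
        self.blocks = [ViTBlock(dim, n_heads, rng, ln_eps=ln_eps) for _ in range(depth)]
        self.norm = LayerNorm(dim, ln_eps)

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return self.norm(x)

    @property
    def attention_stack(self) -> np.ndarray:
        """Last forward pass's attention, shape (L, ..., heads, N, N)."""
        return np.stack([b.attn.last_attention for b in self.blocks])


class BiLSTM(Module):
    """Bidirectional LSTM; feature = [h_T(forward); h_T(backward)]."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        scale = 1.0 / np.sqrt(hidden)
        def init(shape):
            return rng.uniform(-scale, scale, size=shape)
        # gate order: input, forget, cell, output (stacked on last axis)
        self.w_x_f = Parameter(init((d_in, 4 * hidden)))
        self.w_h_f = Parameter(init((hidden, 4 * hidden)))
        self.b_f = Parameter(np.zeros(4 * hidden))
        self.w_x_b = Parameter(init((d_in, 4 * hidden)))
        self.w_h_b = Parameter(init((hidden, 4 * hidden)))
        self.b_b = Parameter(np.zeros(4 * hidden))

    def _run(self, xs, w_x, w_h, b):
        H = self.hidden
        h = Tensor(np.zeros(H, dtype=w_x.data.dtype))
        c = Tensor(np.zeros(H, dtype=w_x.data.dtype))
        for x in xs:
            z = x @ w_x + h @ w_h + b
            i = z[..., 0 * H:1 * H].sigmoid()
            f = z[..., 1 * H:2 * H].sigmoid()
            g = z[..., 2 * H:3 * H].tanh()
            o = z[..., 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h

    def __call__(self, xs: list) -> Tensor:
        """xs: ordered per-time-step tensors, each (D,) or batched (B, D)."""
        xs = [as_tensor(x) for x in xs]
        if not xs:
            raise ValueError("empty sequence")
        h_fwd = self._run(xs, self.w_x_f, self.w_h_f, self.b_f)
        h_bwd = self._run(xs[::-1], self.w_x_b, self.w_h_b, self.b_b)
        return concatenate([h_fwd, h_bwd], axis=-1)


def cross_entropy(logits: Tensor, target: int) -> Tensor:
    """Negative log-likelihood of `target` under softmax(logits) (1-D logits)."""
    return -logits.log_softmax(axis=-1)[int(target)]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 2e-4, betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
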