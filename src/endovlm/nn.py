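"""Neural building blocks used by the multi-task model.

All layers hold their weights as :class:`~endovlm.autodiff.Tensor` leaves and
compose the autodiff primitives, so one `backward()` on a scalar loss yields
gradients for every trainable parameter.  Weights are float32; initialisation
is driven by an explicit :class:`numpy.random.Generator` so models are fully
reproducible from a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

DTYPE = np.float32


def _init(rng: np.random.Generator, shape, scale: float | None = None) -> np.ndarray:
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        scale = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-scale, scale, size=shape).astype(DTYPE)


class Module:
    """Base class with recursive parameter discovery and (de)serialisation."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                yield key, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Tensor):
                        yield f"{key}.{i}", item

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False

    @property
    def frozen(self) -> bool:
        params = self.parameters()
        return bool(params) and not any(p.requires_grad for p in params)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for k, v in state.items():
            own[k].data = np.asarray(v, dtype=own[k].data.dtype)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Tensor(_init(rng, (d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_tokens: int, d: int, rng: np.random.Generator):
        self.weight = Tensor(
            rng.normal(0.0, 0.02, size=(n_tokens, d)).astype(DTYPE),
            requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return ad.take_rows(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(d, dtype=DTYPE), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self._eps) ** -0.5
        return centered * inv * self.gamma + self.beta


def _attention(q: Tensor, k: Tensor, v: Tensor, n_heads: int,
               key_mask: np.ndarray | None = None) -> tuple[Tensor, np.ndarray]:
    """Scaled dot-product attention with head splitting.

    q: (B, Tq, d); k, v: (B, Tk, d); key_mask: (B, Tk) boolean, True = valid.
    Returns (output (B, Tq, d), weights (B, heads, Tq, Tk) as numpy).
    """
    B, Tq, d = q.shape
    Tk = k.shape[1]
    dh = d // n_heads

    def split(x: Tensor) -> Tensor:  # (B,T,d) -> (B,heads,T,dh)
        return x.reshape(B, x.shape[1], n_heads, dh).transpose(0, 2, 1, 3)

    qh, kh, vh = split(q), split(k), split(v)
    scores = qh @ kh.transpose(0, 1, 3, 2) * (1.0 / np.sqrt(dh))
    if key_mask is not None:
        bias = np.where(key_mask[:, None, None, :], 0.0, -1e9).astype(DTYPE)
        scores = scores + Tensor(bias)
    weights = ad.softmax(scores, axis=-1)
    out = weights @ vh
    out = out.transpose(0, 2, 1, 3).reshape(B, Tq, d)
    return out, weights.data


class MultiHeadAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError("embed dim must be divisible by the head count")
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self._heads = n_heads

    def __call__(self, query: Tensor, keys: Tensor,
                 key_mask: np.ndarray | None = None) -> tuple[Tensor, np.ndarray]:
        out, w = _attention(self.wq(query), self.wk(keys), self.wv(keys),
                            self._heads, key_mask)
        return self.wo(out), w


class TransformerBlock(Module):
    """Pre-norm self-attention block with a 2-layer feed-forward.

    `residual_scale` < 1 shrinks the attention/FF output projections at
    init, keeping the block near the identity.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator,
                 ff_mult: int = 2, residual_scale: float = 1.0):
        self.attn = MultiHeadAttention(d, n_heads, rng)
        self.norm1 = LayerNorm(d)
        self.norm2 = LayerNorm(d)
        self.ff1 = Linear(d, ff_mult * d, rng)
        self.ff2 = Linear(ff_mult * d, d, rng)
        if residual_scale != 1.0:
            self.attn.wo.weight.data *= residual_scale
            self.ff2.weight.data *= residual_scale

    def __call__(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        h = self.norm1(x)
        a, _ = self.attn(h, h, key_mask=mask)
        x = x + a
        h = self.norm2(x)
        return x + self.ff2(self.ff1(h).relu())


class LSTM(Module):
    """Stacked LSTM advanced one step at a time (generation-friendly).

    The input-side projection of the first layer can be precomputed for a
    whole teacher-forced sequence (`project_inputs`), turning the per-step
    work into a single hidden-side matmul per layer.
    """

    def __init__(self, d_in: int, d_hidden: int, n_layers: int,
                 rng: np.random.Generator):
        self.layers = []
        for i in range(n_layers):
            di = d_in if i == 0 else d_hidden
            self.layers.append(_LSTMCell(di, d_hidden, rng))
        self.n_layers = n_layers
        self.d_hidden = d_hidden

    def init_state(self, batch: int) -> list[tuple[Tensor, Tensor]]:
        z = Tensor(np.zeros((batch, self.d_hidden), dtype=DTYPE))
        return [(z, z) for _ in range(self.n_layers)]

    def project_inputs(self, x_seq: Tensor) -> Tensor:
        """(B, T, d_in) -> (B, T, 4h): layer-0 input projection, batched."""
        return x_seq @ self.layers[0].w_x

    def step(self, x: Tensor, state: list[tuple[Tensor, Tensor]],
             x_projected: bool = False
             ) -> tuple[Tensor, list[tuple[Tensor, Tensor]]]:
        new_state = []
        inp = x
        for li, (cell, (h, c)) in enumerate(zip(self.layers, state)):
            pre = x_projected and li == 0
            h, c = cell(inp, h, c, input_projected=pre)
            new_state.append((h, c))
            inp = h
        return inp, new_state


class _LSTMCell(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.w_x = Tensor(_init(rng, (d_in, 4 * d_hidden)), requires_grad=True)
        self.w_h = Tensor(_init(rng, (d_hidden, 4 * d_hidden)), requires_grad=True)
        self.b = Tensor(np.zeros(4 * d_hidden, dtype=DTYPE), requires_grad=True)
        self._dh = d_hidden

    def __call__(self, x: Tensor, h: Tensor, c: Tensor,
                 input_projected: bool = False) -> tuple[Tensor, Tensor]:
        xp = x if input_projected else x @ self.w_x
        gates = xp + h @ self.w_h + self.b
        dh = self._dh
        i = gates[:, 0 * dh:1 * dh].sigmoid()
        f = gates[:, 1 * dh:2 * dh].sigmoid()
        g = gates[:, 2 * dh:3 * dh].tanh()
        o = gates[:, 3 * dh:4 * dh].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class Conv2d(Module):
    """Stride-s 2-D convolution via im2col (channels-last input)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, pad: int = 1):
        self.weight = Tensor(_init(rng, (kernel * kernel * c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.c_in = c_in

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, H, W, C) -> (B, Hout, Wout, c_out)."""
        B, H, W, C = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        Hp, Wp = H + 2 * p, W + 2 * p
        Ho, Wo = (Hp - k) // s + 1, (Wp - k) // s + 1
        xp_data = np.zeros((B, Hp, Wp, C), dtype=x.data.dtype)
        xp_data[:, p:p + H, p:p + W, :] = x.data

        weight, bias = self.weight, self.bias

        def forward_cols(arr: np.ndarray) -> np.ndarray:
            cols = np.empty((B, Ho, Wo, k * k * C), dtype=arr.dtype)
            idx = 0
            for di in range(k):
                for dj in range(k):
                    cols[..., idx * C:(idx + 1) * C] = \
                        arr[:, di:di + Ho * s:s, dj:dj + Wo * s:s, :]
                    idx += 1
            return cols

        cols = forward_cols(xp_data)
        out_data = cols.reshape(-1, k * k * C) @ weight.data + bias.data
        out_data = out_data.reshape(B, Ho, Wo, -1)

        def backward(g):
            g2 = g.reshape(-1, g.shape[-1])
            if weight.requires_grad:
                weight._accum(cols.reshape(-1, k * k * C).T @ g2)
            if bias.requires_grad:
                bias._accum(g2.sum(axis=0))
            if x.requires_grad:
                gcols = (g2 @ weight.data.T).reshape(B, Ho, Wo, k * k * C)
                gxp = np.zeros_like(xp_data)
                idx = 0
                for di in range(k):
                    for dj in range(k):
                        gxp[:, di:di + Ho * s:s, dj:dj + Wo * s:s, :] += \
                            gcols[..., idx * C:(idx + 1) * C]
                        idx += 1
                x._accum(gxp[:, p:p + H, p:p + W, :])

        return Tensor._make(out_data, (x, weight, bias), backward)


class RAdam:
    """Rectified Adam (variance-rectified adaptive learning rate)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.rho_inf = 2.0 / (1.0 - self.b2) - 1.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1, b2 = self.b1, self.b2
        rho_t = self.rho_inf - 2.0 * t * b2 ** t / (1.0 - b2 ** t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** t)
            if rho_t > 4.0:
                r = np.sqrt(((rho_t - 4) * (rho_t - 2) * self.rho_inf)
                            / ((self.rho_inf - 4) * (self.rho_inf - 2) * rho_t))
                v_hat = np.sqrt(v / (1 - b2 ** t)) + self.eps
                p.data = p.data - self.lr * r * m_hat / v_hat
            else:
                p.data = p.data - self.lr * m_hat
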