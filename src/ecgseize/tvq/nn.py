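"""Tiny neural-network primitives in numpy with hand-derived gradients.

Just enough machinery for the desk-scale tokenizer and masked-token prior:
linear layers, tanh, token/position embeddings, multi-head self-attention
blocks with residual connections, a softmax cross-entropy head and Adam.
Gradient correctness is guarded by a finite-difference check in the test
suite.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, scale=None):
        s = scale if scale is not None else 1.0 / np.sqrt(n_in)
        self.W = Param(rng.normal(0.0, s, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, d: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ d.reshape(-1, d.shape[-1])
        self.b.grad += d.reshape(-1, d.shape[-1]).sum(axis=0)
        return d @ self.W.value.T

    def params(self):
        return [self.W, self.b]


class Tanh:
    def __init__(self):
        self._y = None

    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, d):
        return d * (1.0 - self._y**2)

    def params(self):
        return []


class MLP:
    """Two-layer perceptron with tanh nonlinearity."""

    def __init__(self, n_in, n_hidden, n_out, rng, out_scale=None):
        self.l1 = Linear(n_in, n_hidden, rng)
        self.act = Tanh()
        self.l2 = Linear(n_hidden, n_out, rng, scale=out_scale)

    def forward(self, x):
        return self.l2.forward(self.act.forward(self.l1.forward(x)))

    def backward(self, d):
        return self.l1.backward(self.act.backward(self.l2.backward(d)))

    def params(self):
        return self.l1.params() + self.l2.params()


class Embedding:
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        self.E = Param(rng.normal(0.0, 0.02, size=(n_tokens, dim)))
        self._ids = None

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.E.value[ids]

    def backward(self, d: np.ndarray) -> None:
        np.add.at(self.E.grad, self._ids, d)

    def params(self):
        return [self.E]


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention:
    """Bidirectional (unmasked) self-attention over the token grid."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.dh = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self._cache = None

    def _split(self, x):
        b, t, c = x.shape
        return x.reshape(b, t, self.n_heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x):
        b, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        attn = _softmax(scores, axis=-1)
        out = attn @ v
        self._cache = (q, k, v, attn)
        return self.wo.forward(self._merge(out))

    def backward(self, d: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        dout = self._split(self.wo.backward(d))
        dattn = dout @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dout
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores /= np.sqrt(self.dh)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = self.wq.backward(self._merge(dq))
        dx += self.wk.backward(self._merge(dk))
        dx += self.wv.backward(self._merge(dv))
        return dx

    def params(self):
        return (
            self.wq.params() + self.wk.params() + self.wv.params() + self.wo.params()
        )


class TransformerBlock:
    """Pre-activationless residual block: x + attn(x), then x + mlp(x)."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.mlp = MLP(dim, 2 * dim, dim, rng)

    def forward(self, x):
        x = x + self.attn.forward(x)
        return x + self.mlp.forward(x)

    def backward(self, d):
        d = d + self.mlp.backward(d)
        return d + self.attn.backward(d)

    def params(self):
        return self.attn.params() + self.mlp.params()


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean NLL over masked positions and its gradient w.r.t. logits.

    ``logits``: (B, T, K); ``targets``: (B, T) ints; ``mask``: (B, T) bool
    selecting the positions that contribute to the loss.
    """
    probs = _softmax(logits, axis=-1)
    b, t, k = logits.shape
    flat = probs.reshape(-1, k)
    idx = np.arange(b * t)
    nll = -np.log(flat[idx, targets.reshape(-1)] + 1e-12).reshape(b, t)
    n = max(1, int(mask.sum()))
    loss = float((nll * mask).sum() / n)
    dlogits = probs.copy()
    dlogits.reshape(-1, k)[idx, targets.reshape(-1)] -= 1.0
    dlogits *= (mask[..., None] / n)
    return loss, dlogits


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
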