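"""Stage 2: bidirectional masked-token prior over token grids.

A tiny transformer (token + position embeddings, two residual
self-attention blocks, a zero-initialized softmax head) is trained to
predict tokens hidden behind a [MASK] symbol from their bidirectional
context, i.e. to minimize the negative log-likelihood of the true tokens
at masked positions.  Because the output head starts at zero, the
untrained prior is exactly uniform: every masked cell scores ln(K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Embedding, Linear, TransformerBlock, _softmax, softmax_cross_entropy


@dataclass(frozen=True)
class PriorSpec:
    """Desk-scale prior configuration (2 layers, 2 heads by default)."""

    codebook_size: int = 16
    height: int = 9  # H of the token grid
    width: int = 16  # frames per context window
    dim: int = 32
    n_layers: int = 2
    n_heads: int = 2
    training_steps: int = 300
    batch_size: int = 8
    lr: float = 3e-3
    mask_ratio: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.mask_ratio < 1.0:
            raise ValueError("mask_ratio must lie in (0, 1)")


class MaskedTokenPrior:
    """p(token | bidirectional context) over H x width token windows."""

    def __init__(self, spec: PriorSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        k = spec.codebook_size
        self.mask_id = k  # vocabulary: 0..K-1 tokens, K = [MASK]
        t = spec.height * spec.width
        self.tok_emb = Embedding(k + 1, spec.dim, rng)
        self.pos_emb = Embedding(t, spec.dim, rng)
        self.blocks = [
            TransformerBlock(spec.dim, spec.n_heads, rng)
            for _ in range(spec.n_layers)
        ]
        # zero-initialized head -> exactly uniform predictions before training
        self.head = Linear(spec.dim, k, rng, scale=0.0)
        self._rng = rng
        self._pos_ids = np.arange(t)
        self.initial_nll_: float | None = None
        self.final_nll_: float | None = None

    # -- forward / backward -------------------------------------------
    def _forward(self, tokens_flat: np.ndarray) -> np.ndarray:
        x = self.tok_emb.forward(tokens_flat) + self.pos_emb.forward(
            np.broadcast_to(self._pos_ids, tokens_flat.shape)
        )
        for blk in self.blocks:
            x = blk.forward(x)
        return self.head.forward(x)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        for blk in reversed(self.blocks):
            d = blk.backward(d)
        self.tok_emb.backward(d)
        self.pos_emb.backward(d)

    def params(self):
        ps = self.tok_emb.params() + self.pos_emb.params() + self.head.params()
        for blk in self.blocks:
            ps += blk.params()
        return ps

    # -- API ------------------------------------------------------------
    def _check_window(self, window: np.ndarray):
        h, w = self.spec.height, self.spec.width
        if window.shape != (h, w):
            raise ValueError(f"token window must be {(h, w)}, got {window.shape}")

    def masked_nll(
        self, window: np.ndarray, mask: np.ndarray
    ) -> np.ndarray:
        """Per-cell NLL of the true tokens at masked cells (others NaN)."""
        out = self.masked_nll_batch(window[None], mask[None])
        return out[0]

    def masked_nll_batch(
        self, windows: np.ndarray, masks: np.ndarray
    ) -> np.ndarray:
        """Vectorized masked NLL over a batch of (H, W) windows."""
        b = len(windows)
        h, w = self.spec.height, self.spec.width
        flat_tokens = windows.reshape(b, h * w)
        flat_masks = masks.reshape(b, h * w)
        inputs = np.where(flat_masks, self.mask_id, flat_tokens)
        logits = self._forward(inputs)
        probs = _softmax(logits, axis=-1)
        idx_b, idx_t = np.nonzero(flat_masks)
        nll = np.full((b, h * w), np.nan)
        nll[idx_b, idx_t] = -np.log(
            probs[idx_b, idx_t, flat_tokens[idx_b, idx_t]] + 1e-12
        )
        return nll.reshape(b, h, w)

    def mean_masked_nll(self, windows: list[np.ndarray], seed: int = 0) -> float:
        """Mean NLL under one deterministic random mask per window."""
        rng = np.random.default_rng(seed)
        total, count = 0.0, 0
        for win in windows:
            self._check_window(win)
            mask = rng.random(win.shape) < self.spec.mask_ratio
            if not mask.any():
                mask[rng.integers(win.shape[0]), rng.integers(win.shape[1])] = True
            nll = self.masked_nll(win, mask)
            total += np.nansum(nll)
            count += int(mask.sum())
        return total / max(count, 1)

    def fit(self, windows: list[np.ndarray]) -> "MaskedTokenPrior":
        spec = self.spec
        wins = np.stack([np.asarray(w, dtype=int) for w in windows])
        for w in wins:
            self._check_window(w)
        b_all, h, wd = wins.shape
        flat = wins.reshape(b_all, h * wd)
        opt = Adam(self.params(), lr=spec.lr)
        self.initial_nll_ = self.mean_masked_nll(list(wins), seed=spec.seed)
        for _ in range(spec.training_steps):
            idx = self._rng.integers(0, b_all, size=min(spec.batch_size, b_all))
            batch = flat[idx]
            mask = self._rng.random(batch.shape) < spec.mask_ratio
            empty = ~mask.any(axis=1)
            mask[empty, 0] = True  # every window contributes
            inputs = np.where(mask, self.mask_id, batch)
            opt.zero_grad()
            logits = self._forward(inputs)
            _, dlogits = softmax_cross_entropy(logits, batch, mask)
            self._backward(dlogits)
            opt.step()
        self.final_nll_ = self.mean_masked_nll(list(wins), seed=spec.seed)
        return self


class UniformPrior:
    """Analytically uniform prior: every masked cell scores exactly ln(K).

    The closed-form numeric anchor for the scoring pipeline.
    """

    def __init__(self, codebook_size: int, height: int, width: int):
        self.spec = PriorSpec(
            codebook_size=codebook_size, height=height, width=width
        )
        self.mask_id = codebook_size

    def _check_window(self, window):
        h, w = self.spec.height, self.spec.width
        if window.shape != (h, w):
            raise ValueError(f"token window must be {(h, w)}, got {window.shape}")

    def masked_nll(self, window, mask):
        return self.masked_nll_batch(window[None], mask[None])[0]

    def masked_nll_batch(self, windows, masks):
        out = np.full(windows.shape, np.nan, dtype=float)
        out[masks.astype(bool)] = np.log(self.spec.codebook_size)
        return out


def train_stage2(
    tokenizer,
    normal_segments: list[np.ndarray],
    mask_ratio: float = 0.3,
    steps: int = 300,
    seed: int = 0,
    width: int = 16,
    **prior_kwargs,
) -> MaskedTokenPrior:
    """Train the masked-token prior on the frozen tokenizer's normal grids.

    Normal segments are tokenized and cut into non-overlapping windows of
    ``width`` frames; the tokenizer itself is never updated.
    """
    spec = PriorSpec(
        codebook_size=tokenizer.spec.codebook_size,
        height=tokenizer.spec.height,
        width=width,
        training_steps=steps,
        mask_ratio=mask_ratio,
        seed=seed,
        **prior_kwargs,
    )
    windows = []
    for seg in normal_segments:
        grid = tokenizer.tokenize(np.asarray(seg, dtype=float)).tokens
        for start in range(0, grid.shape[1] - width + 1, width):
            windows.append(grid[:, start : start + width])
    if not windows:
        raise ValueError("no full token windows; segments too short")
    return MaskedTokenPrior(spec).fit(windows)
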