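"""Stage 1: STFT tokenizer — encoder, EMA vector quantizer, decoder.

The 8 Hz series is mapped to a log-magnitude STFT grid of height
``H = floor(n_fft / 2) + 1``.  Each (frequency, frame) cell is encoded
from its local 3x3 spectrogram patch into a D-dimensional latent, snapped
to the nearest of K codebook prototypes (exponential-moving-average
updates, straight-through gradient), and decoded back to the cell's
magnitude; training minimizes the reconstruction error plus a commitment
term.  The resulting token map s in {1..K}^(H x W) is the discrete
representation the masked-token prior models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .nn import MLP, Adam

_PATCH = 9  # 3x3 spectrogram neighborhood per cell


def latent_height(n_fft: int) -> int:
    """Latent grid height ``floor(n_fft/2) + 1`` (one-sided spectrum bins)."""
    if n_fft < 2:
        raise ValueError("n_fft must be >= 2")
    return n_fft // 2 + 1


@dataclass(frozen=True)
class TokenizerSpec:
    """Desk-scale tokenizer configuration.

    Deliberately tiny: a 2-layer MLP encoder/decoder per spectrogram cell,
    D=8 latent channels and K=16 prototypes train in seconds on one CPU
    while preserving the tokenize -> prior -> masked-likelihood mechanism.
    """

    n_fft: int = 16
    hop: int = 8
    latent_dim: int = 8
    hidden: int = 32
    codebook_size: int = 16
    training_steps: int = 300
    batch_size: int = 256
    lr: float = 5e-3
    commitment: float = 0.25
    ema_decay: float = 0.99
    seed: int = 0

    def __post_init__(self):
        if self.codebook_size < 2:
            raise ValueError("codebook must have K >= 2 prototypes")
        if self.n_fft < 2 or self.hop < 1:
            raise ValueError("invalid STFT geometry")

    @property
    def height(self) -> int:
        return latent_height(self.n_fft)


@dataclass
class TokenGrid:
    """Token map over the (frequency bin, frame) grid plus frame times."""

    tokens: np.ndarray  # (H, W) ints in 0..K-1
    frame_times: np.ndarray  # seconds, length W
    hop: int
    fs: float

    @property
    def shape(self):
        return self.tokens.shape


def stft_logmag(series: np.ndarray, n_fft: int, hop: int, fs: float = 8.0):
    """Log-magnitude STFT grid (H, W) and the frame-center times."""
    x = np.asarray(series, dtype=float)
    if len(x) < n_fft:
        raise ValueError(
            f"series of {len(x)} samples shorter than n_fft={n_fft}"
        )
    f, t, z = sps.stft(
        x,
        fs=fs,
        nperseg=n_fft,
        noverlap=n_fft - hop,
        boundary="zeros",
        padded=True,
    )
    return np.log1p(np.abs(z)), np.asarray(t)


def _cell_patches(grid: np.ndarray) -> np.ndarray:
    """3x3 edge-padded neighborhood of every cell, flattened: (H, W, 9)."""
    padded = np.pad(grid, 1, mode="edge")
    h, w = grid.shape
    patches = np.empty((h, w, _PATCH))
    k = 0
    for di in range(3):
        for dj in range(3):
            patches[:, :, k] = padded[di : di + h, dj : dj + w]
            k += 1
    return patches


class VQTokenizer:
    """Encoder + EMA vector quantizer + decoder over spectrogram cells."""

    def __init__(self, spec: TokenizerSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.encoder = MLP(_PATCH, spec.hidden, spec.latent_dim, rng)
        self.decoder = MLP(spec.latent_dim, spec.hidden, 1, rng)
        self.codebook = rng.normal(
            0.0, 0.1, size=(spec.codebook_size, spec.latent_dim)
        )
        self._ema_counts = np.ones(spec.codebook_size)
        self._ema_sums = self.codebook * self._ema_counts[:, None]
        self._rng = rng
        self.initial_loss_: float | None = None
        self.final_loss_: float | None = None

    # -- encoding -----------------------------------------------------
    def _features(self, series: np.ndarray):
        grid, times = stft_logmag(
            series, self.spec.n_fft, self.spec.hop, fs=self.fs_default
        )
        return grid, times, _cell_patches(grid)

    fs_default = 8.0

    def assign(self, z: np.ndarray) -> np.ndarray:
        """Nearest-codebook index for each latent row."""
        d2 = (
            (z**2).sum(axis=1, keepdims=True)
            - 2.0 * z @ self.codebook.T
            + (self.codebook**2).sum(axis=1)[None, :]
        )
        return np.argmin(d2, axis=1)

    def tokenize(self, series: np.ndarray) -> TokenGrid:
        grid, times, patches = self._features(series)
        h, w, _ = patches.shape
        z = self.encoder.forward(patches.reshape(-1, _PATCH))
        codes = self.assign(z).reshape(h, w)
        return TokenGrid(
            tokens=codes, frame_times=times, hop=self.spec.hop, fs=self.fs_default
        )

    # -- training -----------------------------------------------------
    def _step(self, feats: np.ndarray, targets: np.ndarray, opt: Adam) -> float:
        spec = self.spec
        opt.zero_grad()
        z = self.encoder.forward(feats)
        codes = self.assign(z)
        zq = self.codebook[codes]
        dec_in = z + (zq - z)  # straight-through: value zq, gradient to z
        recon = self.decoder.forward(dec_in)
        err = recon[:, 0] - targets
        n = len(targets)
        recon_loss = float(np.mean(err**2))
        commit = float(np.mean((z - zq) ** 2))
        drecon = (2.0 * err / n)[:, None]
        dz = self.decoder.backward(drecon)  # straight-through path
        dz += 2.0 * spec.commitment * (z - zq) / n
        self.encoder.backward(dz)
        opt.step()
        # EMA codebook update from the batch assignments
        onehot = np.zeros((n, spec.codebook_size))
        onehot[np.arange(n), codes] = 1.0
        counts = onehot.sum(axis=0)
        sums = onehot.T @ z
        d = spec.ema_decay
        self._ema_counts = d * self._ema_counts + (1 - d) * counts
        self._ema_sums = d * self._ema_sums + (1 - d) * sums
        self.codebook = self._ema_sums / np.maximum(self._ema_counts, 1e-6)[:, None]
        return recon_loss + spec.commitment * commit

    def fit(self, normal_segments: list[np.ndarray]) -> "VQTokenizer":
        spec = self.spec
        feats_list, targ_list = [], []
        for seg in normal_segments:
            _, _, patches = self._features(np.asarray(seg, dtype=float))
            flat = patches.reshape(-1, _PATCH)
            feats_list.append(flat)
            targ_list.append(flat[:, _PATCH // 2])  # center cell magnitude
        feats = np.concatenate(feats_list)
        targets = np.concatenate(targ_list)
        # seed the codebook from actual encodings of the data
        z0 = self.encoder.forward(feats[: 4 * spec.codebook_size])
        pick = self._rng.choice(
            len(z0), size=min(spec.codebook_size, len(z0)), replace=False
        )
        self.codebook[: len(pick)] = z0[pick]
        self._ema_sums = self.codebook * self._ema_counts[:, None]
        opt = Adam(self.encoder.params() + self.decoder.params(), lr=spec.lr)
        self.initial_loss_ = self.evaluate(normal_segments)
        for _ in range(spec.training_steps):
            idx = self._rng.integers(0, len(feats), size=min(spec.batch_size, len(feats)))
            self._step(feats[idx], targets[idx], opt)
        self.final_loss_ = self.evaluate(normal_segments)
        return self

    def evaluate(self, segments: list[np.ndarray]) -> float:
        """Reconstruction MSE through the quantized path."""
        losses = []
        for seg in segments:
            _, _, patches = self._features(np.asarray(seg, dtype=float))
            flat = patches.reshape(-1, _PATCH)
            z = self.encoder.forward(flat)
            zq = self.codebook[self.assign(z)]
            recon = self.decoder.forward(zq)[:, 0]
            losses.append(float(np.mean((recon - flat[:, _PATCH // 2]) ** 2)))
        return float(np.mean(losses))

    def codebook_utilization(self, segments: list[np.ndarray]) -> float:
        """Fraction of codebook entries actually used on ``segments``."""
        used = set()
        for seg in segments:
            used.update(np.unique(self.tokenize(np.asarray(seg)).tokens).tolist())
        return len(used) / self.spec.codebook_size


def train_stage1(
    normal_segments: list[np.ndarray], spec: TokenizerSpec | None = None
) -> VQTokenizer:
    """Train the tokenizer on normal (non-ictal, non-SDW) segments only."""
    spec = spec or TokenizerSpec()
    segs = [np.asarray(s, dtype=float) for s in normal_segments]
    for s in segs:
        if len(s) < spec.n_fft:
            raise ValueError(
                f"segment of {len(s)} samples shorter than n_fft={spec.n_fft}"
            )
    return VQTokenizer(spec).fit(segs)
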