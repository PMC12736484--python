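"""Sliding masked-likelihood scoring and the TimeVQVAE-style detector.

With tokenizer and prior frozen, a masking window of half-width alpha
slides along the token grid's time axis; for each center the prior scores
the true tokens hidden at the masked columns by their negative
log-likelihood.  Scores are assigned only to masked cells, averaged over
the sliding passes and summed across the alpha values, then collapsed to
the 8 Hz timeline (column mean over frequency bins, frames expanded by
the STFT hop).  Thresholding plus gap clustering — with an adaptive split
of clusters covering too much of the recording — yields the final alarms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ..clustering import cluster_by_gap, medoid
from ..core import AnomalyEvent
from .prior import train_stage2
from .tokenizer import TokenizerSpec, VQTokenizer, train_stage1

DEFAULT_COVERAGE_LIMIT = 0.5


@dataclass
class AnomalyScoreMap:
    """Aggregated masked-NLL scores over the (bin, frame) grid."""

    scores: np.ndarray  # (H, W_total), NaN where never masked
    frame_times: np.ndarray
    alphas: tuple[int, ...]
    hop: int
    fs: float

    def per_frame(self) -> np.ndarray:
        """Column mean over frequency bins (NaN-safe)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.scores, axis=0)

    def per_sample(self, n_samples: int) -> np.ndarray:
        """Frame scores expanded to the sample timeline by the STFT hop."""
        frames = self.per_frame()
        idx = np.minimum(np.arange(n_samples) // self.hop, len(frames) - 1)
        out = frames[idx]
        return np.nan_to_num(out, nan=0.0)


def score_series(
    series: np.ndarray,
    tokenizer: VQTokenizer,
    prior,
    alphas=(1, 2),
    stride: int = 1,
    batch_windows: int = 64,
) -> AnomalyScoreMap:
    """Sliding masked-NLL map for one series.

    For every center frame ``w`` and half-width ``alpha``, the columns
    ``[w - alpha, w + alpha]`` of a prior-width context window are masked
    and scored; per-cell scores are the mean over all passes that masked
    the cell, summed over ``alphas``.
    """
    if len(alphas) == 0:
        raise ValueError("alphas must be nonempty")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    wp = prior.spec.width
    if stride > wp:
        raise ValueError("stride larger than the prior context width")
    grid = tokenizer.tokenize(np.asarray(series, dtype=float))
    tokens = grid.tokens
    h, w_total = tokens.shape
    if w_total < wp:
        raise ValueError(
            f"series yields {w_total} frames < prior width {wp}"
        )
    total = np.zeros((h, w_total))
    ever = np.zeros((h, w_total), dtype=bool)
    for alpha in alphas:
        acc = np.zeros((h, w_total))
        cnt = np.zeros((h, w_total))
        wins, masks, offsets = [], [], []

        def flush():
            if not wins:
                return
            nll = prior.masked_nll_batch(np.stack(wins), np.stack(masks))
            for b, off in enumerate(offsets):
                m = masks[b]
                vals = np.where(m, np.nan_to_num(nll[b], nan=0.0), 0.0)
                acc[:, off : off + wp] += vals
                cnt[:, off : off + wp] += m
            wins.clear()
            masks.clear()
            offsets.clear()

        for center in range(0, w_total, stride):
            off = int(np.clip(center - wp // 2, 0, w_total - wp))
            lo = max(center - alpha, off)
            hi = min(center + alpha + 1, off + wp)
            if hi <= lo:
                continue
            mask = np.zeros((h, wp), dtype=bool)
            mask[:, lo - off : hi - off] = True
            wins.append(tokens[:, off : off + wp])
            masks.append(mask)
            offsets.append(off)
            if len(wins) >= batch_windows:
                flush()
        flush()
        covered = cnt > 0
        total[covered] += acc[covered] / cnt[covered]
        ever |= covered
    scores = np.where(ever, total, np.nan)
    return AnomalyScoreMap(
        scores=scores,
        frame_times=grid.frame_times,
        alphas=tuple(alphas),
        hop=grid.hop,
        fs=grid.fs,
    )


def _split_oversized(times: list[float], limit_s: float) -> list[list[float]]:
    """Split a cluster at its largest internal gap (ties resolved nearest
    the middle) until every part's span fits the coverage limit."""
    done: list[list[float]] = []
    stack = [list(times)]
    while stack:
        part = stack.pop()
        if len(part) <= 1 or part[-1] - part[0] <= limit_s:
            done.append(part)
            continue
        gaps = np.diff(part)
        best = np.flatnonzero(gaps == gaps.max())
        cut = int(best[np.argmin(np.abs(best - (len(gaps) - 1) / 2))]) + 1
        stack.append(part[:cut])
        stack.append(part[cut:])
    done.sort(key=lambda p: p[0] if p else 0.0)
    return done


def coverage_penalty(
    cluster_spans: list[tuple[float, float]],
    recording_duration: float,
    coverage_limit: float = DEFAULT_COVERAGE_LIMIT,
) -> float:
    """Percentage-point penalty proportional to excess cluster coverage."""
    excess = 0.0
    for start, end in cluster_spans:
        span = max(0.0, end - start)
        excess += max(0.0, span - coverage_limit * recording_duration)
    return 100.0 * excess / max(recording_duration, 1e-9)


def detect(
    score_map: AnomalyScoreMap,
    tau: float,
    n_samples: int,
    delta_t: float = 30.0,
    coverage_limit: float = DEFAULT_COVERAGE_LIMIT,
) -> list[AnomalyEvent]:
    """Threshold the score map and gap-cluster the alarms.

    Sample indices scoring above ``tau`` are clustered with gap
    ``delta_t``; clusters spanning more than ``coverage_limit`` of the
    recording are split at their largest internal gaps before reporting.
    Each cluster is reported at its temporal medoid.
    """
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    per_sample = score_map.per_sample(n_samples)
    fs = score_map.fs
    duration = n_samples / fs
    idx_above = np.flatnonzero(per_sample > tau)
    if len(idx_above) == 0:
        return []
    times = (idx_above / fs).tolist()
    events = []
    for cluster in cluster_by_gap(times, delta_t):
        member_times = [times[i] for i in cluster]
        for part in _split_oversized(member_times, coverage_limit * duration):
            rep_t = part[medoid(part)]
            rep_idx = int(round(rep_t * fs))
            events.append(
                AnomalyEvent(
                    index=rep_idx,
                    score=float(per_sample[min(rep_idx, n_samples - 1)]),
                    detector="tvq",
                    stage="clustered",
                    interval=(part[0], part[-1] + 1.0 / fs),
                )
            )
    return events


class TimeVQVAEDetector(BaseEstimator):
    """Two-stage tokenizer + masked-token prior anomaly detector.

    :meth:`fit` takes a list of normal (non-ictal, non-SDW) series
    segments and trains stage 1 (tokenizer) then stage 2 (prior);
    :meth:`score_samples` returns the per-sample masked-NLL score of a
    series; :meth:`detect` thresholds at ``tau`` (or the fitted training
    percentile) and clusters the alarms.

    Attributes (after :meth:`fit`)
    ------------------------------
    tokenizer_, prior_ : the trained stages.
    train_scores_ : pooled per-sample scores on the training segments,
        the reference distribution for percentile thresholds.
    """

    def __init__(
        self,
        n_fft: int = 16,
        hop: int = 8,
        codebook_size: int = 16,
        latent_dim: int = 8,
        stage1_steps: int = 300,
        prior_width: int = 16,
        prior_dim: int = 32,
        prior_layers: int = 2,
        prior_heads: int = 2,
        stage2_steps: int = 300,
        mask_ratio: float = 0.3,
        alphas=(1, 2),
        stride: int = 1,
        tau_percentile: float = 0.995,
        delta_t: float = 30.0,
        coverage_limit: float = DEFAULT_COVERAGE_LIMIT,
        fs: float = 8.0,
        seed: int = 0,
    ):
        self.n_fft = n_fft
        self.hop = hop
        self.codebook_size = codebook_size
        self.latent_dim = latent_dim
        self.stage1_steps = stage1_steps
        self.prior_width = prior_width
        self.prior_dim = prior_dim
        self.prior_layers = prior_layers
        self.prior_heads = prior_heads
        self.stage2_steps = stage2_steps
        self.mask_ratio = mask_ratio
        self.alphas = alphas
        self.stride = stride
        self.tau_percentile = tau_percentile
        self.delta_t = delta_t
        self.coverage_limit = coverage_limit
        self.fs = fs
        self.seed = seed

    def fit(self, X, y=None):
        segments = [np.asarray(s, dtype=float) for s in (X if isinstance(X, list) else [X])]
        spec = TokenizerSpec(
            n_fft=self.n_fft,
            hop=self.hop,
            latent_dim=self.latent_dim,
            codebook_size=self.codebook_size,
            training_steps=self.stage1_steps,
            seed=self.seed,
        )
        self.tokenizer_ = train_stage1(segments, spec)
        self.prior_ = train_stage2(
            self.tokenizer_,
            segments,
            mask_ratio=self.mask_ratio,
            steps=self.stage2_steps,
            seed=self.seed,
            width=self.prior_width,
            dim=self.prior_dim,
            n_layers=self.prior_layers,
            n_heads=self.prior_heads,
        )
        scores = []
        for seg in segments:
            if len(seg) // self.hop >= self.prior_width:
                m = self.score_map(seg)
                scores.append(m.per_sample(len(seg)))
        self.train_scores_ = (
            np.concatenate(scores) if scores else np.empty(0)
        )
        return self

    def score_map(self, series) -> AnomalyScoreMap:
        return score_series(
            np.asarray(series, dtype=float),
            self.tokenizer_,
            self.prior_,
            alphas=self.alphas,
            stride=self.stride,
        )

    def score_samples(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        return self.score_map(x).per_sample(len(x))

    def detect(self, X, tau: float | None = None) -> list[AnomalyEvent]:
        x = np.asarray(X, dtype=float)
        if tau is None:
            if len(self.train_scores_) == 0:
                raise ValueError("no training score distribution; pass tau")
            tau = float(np.quantile(self.train_scores_, self.tau_percentile))
        return detect(
            self.score_map(x),
            tau=tau,
            n_samples=len(x),
            delta_t=self.delta_t,
            coverage_limit=self.coverage_limit,
        )
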