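"""Matrix-profile discord detection.

The matrix profile assigns every subsequence start its z-normalized
Euclidean distance to the nearest non-trivial match; large values mark
discords, the candidate anomalies.  Candidates pass a global percentile
threshold and a greedy overlap filter, then a min-run temporal clustering
that requires ``min_n`` near-consecutive anomalies to confirm an event and
reports the run at the nearest integer to its mean index.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

from .core import AnomalyEvent, PreprocessedSeries

_VAR_TOL = 1e-12


def _as_series(series) -> np.ndarray:
    if isinstance(series, PreprocessedSeries):
        return series.samples
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    return arr


def _subsequence_stats(x: np.ndarray, m: int):
    """Windowed mean, SD and the fallback scale used for flat windows."""
    win = sliding_window_view(x, m)
    mu = win.mean(axis=1)
    sd = win.std(axis=1)
    scale = np.where(sd > _VAR_TOL, sd, 1.0)  # mean-center flat windows
    return win, mu, sd, scale


def matrix_profile(
    series,
    m: int,
    exclusion_zone: int | None = None,
    block_size: int = 256,
) -> np.ndarray:
    """Exact matrix profile under z-normalized Euclidean distance.

    ``exclusion_zone`` (default ``ceil(m/2)``) suppresses trivial matches
    around each start index.  Zero-variance subsequences fall back to
    mean-centering with unit scale and are assigned distance 0 so rail
    artifacts never surface as discords.
    """
    x = _as_series(series)
    n = len(x)
    if m < 3:
        raise ValueError("subsequence length m must be >= 3")
    if n < 2 * m:
        raise ValueError(f"series of length {n} too short for m={m}")
    excl = math.ceil(m / 2) if exclusion_zone is None else int(exclusion_zone)

    win, mu, sd, scale = _subsequence_stats(x, m)
    p = n - m + 1
    # squared norm of each (fallback-)normalized subsequence
    norm_sq = m * (sd / scale) ** 2

    profile = np.full(p, np.inf)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        q = win[start:stop] @ win.T  # (b, p) raw dot products
        cross = (q - m * np.outer(mu[start:stop], mu)) / np.outer(
            scale[start:stop], scale
        )
        d2 = norm_sq[start:stop, None] + norm_sq[None, :] - 2.0 * cross
        np.maximum(d2, 0.0, out=d2)
        idx = np.arange(start, stop)[:, None]
        jdx = np.arange(p)[None, :]
        d2[np.abs(idx - jdx) < excl] = np.inf
        profile[start:stop] = np.sqrt(d2.min(axis=1))
    profile[sd <= _VAR_TOL] = 0.0
    return profile


def brute_force_profile(
    series, m: int, exclusion_zone: int | None = None
) -> np.ndarray:
    """Reference all-pairs computation (O(n^2 m)); test oracle only."""
    x = _as_series(series)
    n = len(x)
    excl = math.ceil(m / 2) if exclusion_zone is None else int(exclusion_zone)
    p = n - m + 1
    subs = []
    flat = []
    for i in range(p):
        s = x[i : i + m]
        sd = s.std()
        flat.append(sd <= _VAR_TOL)
        subs.append((s - s.mean()) / (sd if sd > _VAR_TOL else 1.0))
    out = np.full(p, np.inf)
    for i in range(p):
        best = np.inf
        for j in range(p):
            if abs(i - j) < excl:
                continue
            d = float(np.linalg.norm(subs[i] - subs[j]))
            best = min(best, d)
        out[i] = best
    out[np.asarray(flat)] = 0.0
    return out


def select_discords(
    profile: np.ndarray,
    m: int,
    percentile: float = 0.98,
    max_overlap: float = 0.9,
    detector: str = "mp",
) -> list[AnomalyEvent]:
    """Percentile threshold plus greedy overlap suppression.

    Candidates at or above the global ``percentile`` of the profile are
    accepted in descending score order (ties to the earlier index); a
    candidate is discarded when its ``[i, i+m)`` span overlaps an accepted
    one by more than ``max_overlap * m`` samples.
    """
    prof = np.asarray(profile, dtype=float)
    if len(prof) == 0:
        return []
    if not 0.0 <= percentile <= 1.0:
        raise ValueError("percentile outside [0, 1]")
    finite = prof[np.isfinite(prof)]
    if len(finite) == 0:
        return []
    threshold = float(np.quantile(finite, percentile))
    cand = [i for i in range(len(prof)) if np.isfinite(prof[i]) and prof[i] >= threshold]
    cand.sort(key=lambda i: (-prof[i], i))
    kept: list[int] = []
    for i in cand:
        ok = True
        for j in kept:
            overlap = max(0, m - abs(i - j))
            if overlap > max_overlap * m:
                ok = False
                break
        if ok:
            kept.append(i)
    kept.sort()
    return [
        AnomalyEvent(index=i, score=float(prof[i]), detector=detector, stage="raw")
        for i in kept
    ]


def cluster_min_run(
    events: list[AnomalyEvent],
    min_n: int = 3,
    max_gap_s: float = 2.0,
    fs: float = 8.0,
    span_s: float | None = None,
) -> list[AnomalyEvent]:
    """Min-run temporal clustering of raw anomalies.

    Maximal runs whose successive index gaps are at most ``max_gap_s``
    seconds form candidate events; runs with fewer than ``min_n`` members
    are dropped, and each survivor is reported at the nearest integer to
    its mean index with an interval spanning the run.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    evs = sorted(events, key=lambda e: e.index)
    out: list[AnomalyEvent] = []
    run: list[AnomalyEvent] = []

    def flush(run):
        if len(run) >= min_n:
            idx = int(round(float(np.mean([e.index for e in run]))))
            start = min(
                e.interval[0] if e.interval else e.index / fs for e in run
            )
            end = max(
                e.interval[1] if e.interval else (e.index + 1) / fs for e in run
            )
            if span_s is not None:
                end = max(end, run[-1].index / fs + span_s)
            out.append(
                AnomalyEvent(
                    index=idx,
                    score=max(e.score for e in run),
                    detector=run[0].detector,
                    stage="clustered",
                    interval=(start, end),
                )
            )

    for e in evs:
        if run and (e.index - run[-1].index) / fs > max_gap_s:
            flush(run)
            run = []
        run.append(e)
    if run:
        flush(run)
    return out


class MatrixProfileDetector(BaseEstimator):
    """Matrix-profile discord detector with min-run clustering.

    Parameters
    ----------
    m : subsequence length in samples (default 80 = 10 s at 8 Hz, spanning
        several cardiac cycles of the decimated envelope).
    percentile : global discord-score threshold quantile.
    max_overlap : overlap-filter limit as a fraction of ``m``.
    min_n, max_gap_s : min-run clustering parameters.
    fs : sampling rate of the input series (Hz).

    Attributes (after :meth:`fit`)
    ------------------------------
    profile_ : the matrix profile of the fitted series.
    events_ : post-clustering anomaly events.
    raw_events_ : thresholded events before clustering.
    """

    def __init__(
        self,
        m: int = 80,
        percentile: float = 0.98,
        max_overlap: float = 0.9,
        min_n: int = 2,
        max_gap_s: float = 2.0,
        exclusion_zone: int | None = None,
        fs: float = 8.0,
    ):
        self.m = m
        self.percentile = percentile
        self.max_overlap = max_overlap
        self.min_n = min_n
        self.max_gap_s = max_gap_s
        self.exclusion_zone = exclusion_zone
        self.fs = fs

    def fit(self, X, y=None):
        x = _as_series(X)
        self.n_samples_ = len(x)
        self.profile_ = matrix_profile(x, self.m, self.exclusion_zone)
        self.raw_events_ = select_discords(
            self.profile_, self.m, self.percentile, self.max_overlap
        )
        self.events_ = cluster_min_run(
            self.raw_events_,
            self.min_n,
            self.max_gap_s,
            self.fs,
            span_s=self.m / self.fs,
        )
        return self

    def score_samples(self, X=None) -> np.ndarray:
        """Per-sample discord score (profile padded to series length)."""
        if X is not None:
            self.fit(X)
        pad = self.n_samples_ - len(self.profile_)
        return np.concatenate([self.profile_, np.full(pad, self.profile_[-1])])

    def detect(self, X=None) -> list[AnomalyEvent]:
        if X is not None:
            self.fit(X)
        return self.events_
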