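"""Multi-length discord search (extended MADRID).

Discords are computed for every subsequence length of a grid
``m_min..m_max`` and pooled after dividing each length's distances by
``sqrt(m)`` so magnitudes are comparable across lengths.  Candidate
anomalies then pass a three-stage selection: (1) a global percentile
threshold over all (length, index) cells, (2) per-length top-k ranking,
(3) a greedy overlap constraint discarding candidates that overlap an
already accepted interval by more than 25% (of the shorter interval).
The surviving list feeds the shared gap clustering with temporal-medoid
representatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .clustering import cluster_by_gap, medoid
from .core import AnomalyEvent
from .matrix_profile import _as_series, matrix_profile

DEFAULT_M_GRID = (24, 48, 80, 120)  # 3-15 s at 8 Hz
DEFAULT_OVERLAP_LIMIT = 0.25


@dataclass
class MultiLengthDiscordTable:
    """Length-normalized discord scores per (subsequence length, start)."""

    lengths: list[int]
    scores: dict[int, np.ndarray] = field(default_factory=dict)
    normalization: str = "sqrt_m"

    def cells(self):
        """Iterate (length, index, score) over every finite cell."""
        for m in self.lengths:
            row = self.scores[m]
            for i in range(len(row)):
                if np.isfinite(row[i]):
                    yield m, i, float(row[i])

    def all_scores(self) -> np.ndarray:
        return np.concatenate(
            [self.scores[m][np.isfinite(self.scores[m])] for m in self.lengths]
        )


def multi_length_discords(
    series,
    m_min: int = DEFAULT_M_GRID[0],
    m_max: int = DEFAULT_M_GRID[-1],
    step: int | None = None,
    m_grid=None,
) -> MultiLengthDiscordTable:
    """Discord scores for each length of the grid, normalized by sqrt(m).

    Either pass an explicit ``m_grid`` or ``m_min``/``m_max``/``step``.
    Lengths too long for the series are skipped with a warning rather than
    failing the whole table.
    """
    import warnings

    x = _as_series(series)
    if m_grid is None:
        if step is None:
            m_grid = [m for m in DEFAULT_M_GRID if m_min <= m <= m_max]
            if not m_grid:
                m_grid = [m_min]
        else:
            if step < 1:
                raise ValueError("step must be >= 1")
            m_grid = list(range(m_min, m_max + 1, step))
    m_grid = sorted(set(int(m) for m in m_grid))
    if m_grid[0] < 3:
        raise ValueError("subsequence lengths must be >= 3")
    table = MultiLengthDiscordTable(lengths=[])
    for m in m_grid:
        if len(x) < 2 * m:
            warnings.warn(
                f"series of length {len(x)} too short for m={m}; skipped",
                stacklevel=2,
            )
            continue
        table.lengths.append(m)
        table.scores[m] = matrix_profile(x, m) / np.sqrt(m)
    if not table.lengths:
        raise ValueError("series too short for every requested length")
    return table


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def select_anomalies(
    table: MultiLengthDiscordTable,
    global_percentile: float = 0.99,
    k: int = 5,
    overlap_limit: float = DEFAULT_OVERLAP_LIMIT,
    fs: float = 8.0,
) -> list[AnomalyEvent]:
    """Three-stage anomaly selection over the multi-length table.

    Ties in score are broken toward the shorter length, then the earlier
    index, keeping the selection deterministic.
    """
    if not 0.0 <= global_percentile <= 1.0:
        raise ValueError("global_percentile outside [0, 1]")
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k == 0:
        return []
    pooled = table.all_scores()
    if len(pooled) == 0:
        return []
    threshold = float(np.quantile(pooled, global_percentile))
    # stage 1: global percentile filter over all cells
    surviving = [
        (m, i, s) for m, i, s in table.cells() if s >= threshold
    ]
    # stage 2: per-length top-k by score (ties to earlier index)
    per_length: list[tuple[int, int, float]] = []
    for m in table.lengths:
        cells = [c for c in surviving if c[0] == m]
        cells.sort(key=lambda c: (-c[2], c[1]))
        per_length.extend(cells[:k])
    # stage 3: greedy overlap constraint, descending score
    per_length.sort(key=lambda c: (-c[2], c[0], c[1]))
    accepted: list[tuple[int, int, float]] = []
    for m, i, s in per_length:
        span = (i, i + m)
        ok = True
        for am, ai, _ in accepted:
            other = (ai, ai + am)
            shorter = min(m, am)
            if _overlap_len(span, other) > overlap_limit * shorter:
                ok = False
                break
        if ok:
            accepted.append((m, i, s))
    accepted.sort(key=lambda c: c[1])
    return [
        AnomalyEvent(
            index=i,
            score=s,
            detector="madrid",
            stage="raw",
            interval=(i / fs, (i + m) / fs),
        )
        for m, i, s in accepted
    ]


class MadridDetector(BaseEstimator):
    """Multi-length discord detector with gap clustering post-processing.

    Parameters
    ----------
    m_grid : subsequence lengths in samples.
    global_percentile : pooled score threshold quantile (stage 1).
    top_k : per-length candidate cap (stage 2).
    overlap_limit : maximal allowed interval overlap fraction (stage 3).
    delta_t : clustering gap in seconds; ``None`` skips clustering.
    fs : sampling rate of the input series.

    Attributes (after :meth:`fit`)
    ------------------------------
    table_ : the multi-length discord table.
    raw_events_ : three-stage selection output.
    events_ : medoid representatives after gap clustering.
    """

    def __init__(
        self,
        m_grid=DEFAULT_M_GRID,
        global_percentile: float = 0.99,
        top_k: int = 5,
        overlap_limit: float = DEFAULT_OVERLAP_LIMIT,
        delta_t: float | None = 30.0,
        fs: float = 8.0,
    ):
        self.m_grid = m_grid
        self.global_percentile = global_percentile
        self.top_k = top_k
        self.overlap_limit = overlap_limit
        self.delta_t = delta_t
        self.fs = fs

    def fit(self, X, y=None):
        x = _as_series(X)
        self.n_samples_ = len(x)
        self.table_ = multi_length_discords(x, m_grid=self.m_grid)
        self.raw_events_ = select_anomalies(
            self.table_,
            self.global_percentile,
            self.top_k,
            self.overlap_limit,
            self.fs,
        )
        if self.delta_t is None:
            self.events_ = list(self.raw_events_)
        else:
            times = [e.index / self.fs for e in self.raw_events_]
            reps = []
            for cluster in cluster_by_gap(times, self.delta_t):
                members = [self.raw_events_[i] for i in cluster]
                rep = members[medoid([times[i] for i in cluster])]
                reps.append(
                    AnomalyEvent(
                        index=rep.index,
                        score=rep.score,
                        detector="madrid",
                        stage="clustered",
                        interval=rep.interval,
                    )
                )
            self.events_ = reps
        return self

    def detect(self, X=None) -> list[AnomalyEvent]:
        if X is not None:
            self.fit(X)
        return self.events_
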