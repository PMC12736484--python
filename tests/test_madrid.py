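"""Multi-length discord search: per-length oracles and three-stage selection."""

import itertools

import numpy as np
import pytest

from ecgseize.madrid import (
    MultiLengthDiscordTable,
    multi_length_discords,
    select_anomalies,
)
from ecgseize.matrix_profile import brute_force_profile, matrix_profile


def reference_selection(table, global_percentile, k, overlap_limit):
    """Independent enumeration of the three selection stages."""
    cells = [(m, i, s) for m, i, s in table.cells()]
    pooled = np.array([s for _, _, s in cells])
    thr = np.quantile(pooled, global_percentile)
    stage1 = [c for c in cells if c[2] >= thr]
    stage2 = []
    for m in table.lengths:
        of_len = sorted(
            [c for c in stage1 if c[0] == m], key=lambda c: (-c[2], c[1])
        )
        stage2.extend(of_len[:k])
    stage2.sort(key=lambda c: (-c[2], c[0], c[1]))
    accepted = []
    for m, i, s in stage2:
        ok = True
        for am, ai, _ in accepted:
            lo = max(i, ai)
            hi = min(i + m, ai + am)
            if max(0, hi - lo) > overlap_limit * min(m, am):
                ok = False
        if ok:
            accepted.append((m, i, s))
    return sorted((i, m) for m, i, _ in accepted)


class TestMultiLengthDiscords:
    def test_degenerate_range_equals_single_length_profile(self, rng):
        x = rng.normal(size=300)
        table = multi_length_discords(x, m_grid=[24])
        assert table.lengths == [24]
        assert np.allclose(
            table.scores[24], matrix_profile(x, 24) / np.sqrt(24)
        )

    def test_row_widths_are_n_minus_m_plus_one(self, rng):
        x = rng.normal(size=1000)
        table = multi_length_discords(x, m_grid=[16, 32, 64])
        assert [len(table.scores[m]) for m in (16, 32, 64)] == [985, 969, 937]

    def test_transient_is_argmax_at_every_length(self):
        rng = np.random.default_rng(5)
        x = np.sin(2 * np.pi * np.arange(900) / 45) + 0.01 * rng.normal(size=900)
        x[450:470] += 3.0
        table = multi_length_discords(x, m_grid=[16, 32, 64])
        for m in table.lengths:
            peak = int(np.argmax(table.scores[m]))
            assert 450 - m < peak < 470
            assert np.allclose(
                table.scores[m], brute_force_profile(x, m) / np.sqrt(m), atol=1e-6
            )

    def test_overlong_lengths_skipped_with_warning(self, rng):
        x = rng.normal(size=100)
        with pytest.warns(UserWarning):
            table = multi_length_discords(x, m_grid=[16, 80])
        assert table.lengths == [16]


def _table(rows):
    """Build a table from {length: scores} dicts."""
    t = MultiLengthDiscordTable(lengths=sorted(rows))
    for m, scores in rows.items():
        t.scores[m] = np.asarray(scores, dtype=float)
    return t


class TestSelectAnomalies:
    def test_k_zero_returns_empty(self):
        t = _table({8: [1.0, 2.0, 3.0]})
        assert select_anomalies(t, 0.5, k=0) == []

    def test_near_identical_intervals_keep_one(self):
        # candidates at indices 2 and 3 overlap by 7/8 of their length
        t = _table({8: [0.0, 0.0, 5.0, 4.9, 0.0]})
        events = select_anomalies(t, 0.0, k=4, overlap_limit=0.25)
        assert [e.index for e in events] == [2]

    def test_hand_built_table_matches_exhaustive_reference(self):
        t = _table({4: [0.9, 0.1, 0.7, 0.3, 0.8], 8: [0.6, 0.95]})
        for pct, k in itertools.product((0.0, 0.4, 0.8), (1, 2, 5)):
            got = sorted(
                (e.index, round(e.interval[1] * 8 - e.index)) for e in
                select_anomalies(t, pct, k=k, overlap_limit=0.25, fs=8.0)
            )
            want = reference_selection(t, pct, k, 0.25)
            assert got == want, (pct, k)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_tables_match_reference(self, seed):
        rng = np.random.default_rng(seed)
        t = _table({6: rng.random(30), 12: rng.random(24), 20: rng.random(16)})
        for pct, k in itertools.product((0.0, 0.5, 0.9), (1, 3, 10)):
            got = sorted(
                (e.index, round(e.interval[1] * 8 - e.index))
                for e in select_anomalies(t, pct, k=k, fs=8.0)
            )
            assert got == reference_selection(t, pct, k, 0.25)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_stage_monotonicity_and_overlap_freedom(self, seed):
        rng = np.random.default_rng(seed)
        t = _table({8: rng.random(60), 16: rng.random(50)})
        sizes_pct = [
            len(select_anomalies(t, pct, k=10)) for pct in (0.0, 0.3, 0.6, 0.9)
        ]
        assert sizes_pct == sorted(sizes_pct, reverse=True)
        sizes_k = [len(select_anomalies(t, 0.2, k=k)) for k in (0, 1, 3, 8)]
        assert sizes_k == sorted(sizes_k)
        events = select_anomalies(t, 0.0, k=10)
        spans = [(e.interval[0] * 8, e.interval[1] * 8) for e in events]
        for (a0, a1), (b0, b1) in itertools.combinations(spans, 2):
            overlap = max(0.0, min(a1, b1) - max(a0, b0))
            assert overlap <= 0.25 * min(a1 - a0, b1 - b0) + 1e-9

    def test_invalid_arguments_rejected(self):
        t = _table({8: [1.0, 2.0]})
        with pytest.raises(ValueError):
            select_anomalies(t, 1.5, k=1)
        with pytest.raises(ValueError):
            select_anomalies(t, 0.5, k=-1)
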