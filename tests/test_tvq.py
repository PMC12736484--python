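"""Tokenizer, masked-token prior and sliding masked-NLL scoring."""

import numpy as np
import pytest

from ecgseize.tvq import (
    AnomalyScoreMap,
    MaskedTokenPrior,
    PriorSpec,
    TokenizerSpec,
    UniformPrior,
    detect,
    latent_height,
    score_series,
    train_stage1,
    train_stage2,
)
from ecgseize.tvq.nn import softmax_cross_entropy


@pytest.fixture(scope="module")
def trained_stages(baseline_series):
    spec = TokenizerSpec(training_steps=200, seed=0)
    tokenizer = train_stage1([baseline_series], spec)
    prior = train_stage2(tokenizer, [baseline_series], steps=200, seed=0)
    return tokenizer, prior


class TestLatentHeight:
    @pytest.mark.parametrize("n_fft,expected", [(8, 5), (7, 4), (256, 129)])
    def test_formula(self, n_fft, expected):
        assert latent_height(n_fft) == expected

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            latent_height(1)


class TestStage1:
    def test_reconstruction_loss_halves(self, trained_stages):
        tokenizer, _ = trained_stages
        assert tokenizer.final_loss_ < 0.5 * tokenizer.initial_loss_

    def test_two_regime_signal_uses_both_codes(self):
        t = np.arange(4000) / 8.0
        x = np.sin(2 * np.pi * 0.5 * t)
        x[2000:] *= 4.0  # second amplitude regime
        spec = TokenizerSpec(codebook_size=2, training_steps=200, seed=1)
        tok = train_stage1([x], spec)
        assert tok.codebook_utilization([x]) == 1.0

    def test_same_data_and_seed_identical_codebook(self, baseline_series):
        spec = TokenizerSpec(training_steps=60, seed=3)
        a = train_stage1([baseline_series], spec)
        b = train_stage1([baseline_series], spec)
        assert np.array_equal(a.codebook, b.codebook)

    def test_segment_shorter_than_nfft_rejected(self):
        with pytest.raises(ValueError):
            train_stage1([np.zeros(8)], TokenizerSpec(n_fft=16))


class TestStage2:
    def test_untrained_prior_is_exactly_uniform(self):
        spec = PriorSpec(codebook_size=16, height=4, width=6, dim=16)
        prior = MaskedTokenPrior(spec)
        win = np.zeros((4, 6), dtype=int)
        mask = np.ones((4, 6), dtype=bool)
        nll = prior.masked_nll(win, mask)
        assert np.allclose(nll, np.log(16), atol=1e-9)

    def test_training_beats_uniform_guessing(self, trained_stages):
        _, prior = trained_stages
        k = prior.spec.codebook_size
        assert prior.initial_nll_ == pytest.approx(np.log(k), abs=1e-6)
        assert prior.final_nll_ < np.log(k)

    def test_shuffled_tokens_score_no_better_than_intact(
        self, trained_stages, baseline_series
    ):
        tokenizer, prior = trained_stages
        grid = tokenizer.tokenize(baseline_series).tokens
        w = prior.spec.width
        win = grid[:, :w]
        rng = np.random.default_rng(0)
        shuffled = rng.permuted(win.ravel()).reshape(win.shape)
        mask = rng.random(win.shape) < 0.3
        mask[0, 0] = True
        intact = np.nanmean(prior.masked_nll(win, mask))
        perm = np.nanmean(prior.masked_nll(shuffled, mask))
        assert perm >= intact

    def test_invalid_mask_ratio_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(mask_ratio=1.5)

    def test_gradients_match_finite_differences(self):
        spec = PriorSpec(
            codebook_size=5, height=3, width=4, dim=8, n_layers=1,
            n_heads=2, seed=0,
        )
        prior = MaskedTokenPrior(spec)
        rng = np.random.default_rng(1)
        # move the zero-initialized head so gradients flow everywhere
        prior.head.W.value = rng.normal(0, 0.3, prior.head.W.value.shape)
        tokens = rng.integers(0, 5, size=(2, 12))
        mask = rng.random((2, 12)) < 0.4
        mask[:, 0] = True
        inputs = np.where(mask, prior.mask_id, tokens)

        def loss():
            logits = prior._forward(inputs)
            return softmax_cross_entropy(logits, tokens, mask)

        for p in prior.params():
            p.grad[...] = 0.0
        value, dlogits = loss()
        prior._backward(dlogits)
        eps = 1e-6
        for p in prior.params()[:6]:
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            idx = rng.integers(0, len(flat), size=3)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                up, _ = loss()
                flat[i] = orig - eps
                dn, _ = loss()
                flat[i] = orig
                fd = (up - dn) / (2 * eps)
                assert gflat[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestScoring:
    def test_uniform_prior_closed_form(self, trained_stages, baseline_series):
        tokenizer, _ = trained_stages
        h = tokenizer.spec.height
        uniform = UniformPrior(tokenizer.spec.codebook_size, h, 16)
        smap = score_series(
            baseline_series, tokenizer, uniform, alphas=(1,), stride=1
        )
        covered = np.isfinite(smap.scores)
        assert covered.any()
        k = tokenizer.spec.codebook_size
        assert np.allclose(smap.scores[covered], np.log(k), atol=1e-9)

    def test_sum_over_alpha_linearity(self, trained_stages, baseline_series):
        tokenizer, prior = trained_stages
        one = score_series(baseline_series, tokenizer, prior, alphas=(1,))
        two = score_series(baseline_series, tokenizer, prior, alphas=(1, 1))
        covered = np.isfinite(one.scores)
        assert np.allclose(two.scores[covered], 2 * one.scores[covered], atol=1e-9)

    def test_stride_larger_than_width_rejected(self, trained_stages, baseline_series):
        tokenizer, prior = trained_stages
        with pytest.raises(ValueError):
            score_series(baseline_series, tokenizer, prior, stride=99)
        with pytest.raises(ValueError):
            score_series(baseline_series, tokenizer, prior, alphas=())


def _score_map(frame_scores):
    scores = np.tile(np.asarray(frame_scores, dtype=float), (3, 1))
    w = scores.shape[1]
    return AnomalyScoreMap(
        scores=scores,
        frame_times=np.arange(w, dtype=float),
        alphas=(1,),
        hop=8,
        fs=8.0,
    )


class TestDetect:
    def test_tau_above_max_yields_nothing(self):
        smap = _score_map([1.0, 2.0, 3.0, 2.0])
        assert detect(smap, tau=10.0, n_samples=32) == []

    def test_two_bumps_give_two_events_at_medoids(self):
        frames = np.zeros(40)
        frames[5:8] = 5.0
        frames[30:33] = 4.0
        smap = _score_map(frames)
        events = detect(smap, tau=1.0, n_samples=320, delta_t=10.0)
        assert len(events) == 2
        times = sorted(e.index / 8.0 for e in events)
        assert 5.0 <= times[0] < 8.0
        assert 30.0 <= times[1] < 33.0

    def test_oversized_cluster_is_split(self):
        frames = np.full(40, 2.0)  # everything above threshold
        smap = _score_map(frames)
        duration = 320 / 8.0
        events = detect(
            smap, tau=1.0, n_samples=320, delta_t=duration, coverage_limit=0.5
        )
        assert len(events) >= 2  # one all-covering cluster must not survive
        for e in events:
            assert e.interval[1] - e.interval[0] <= 0.5 * duration + 0.5

    def test_non_finite_tau_rejected(self):
        with pytest.raises(ValueError):
            detect(_score_map([1.0]), tau=np.inf, n_samples=8)
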