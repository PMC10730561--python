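import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import aadkit as ak
from aadkit.core_io import ParameterError
from aadkit.offline_decoder import pearson
from aadkit.preprocessing import zscore
from aadkit.realtime_decoder import (
    apply_ema,
    enumerate_windows,
    fit_snippet_decoder,
    stream_decode,
    train_realtime_decoder,
    window_accuracy,
)
from conftest import small_dataset
from test_offline_decoder import ridge_oracle


class TestWindows:
    def test_published_configuration_yields_46(self):
        wins = enumerate_windows(60.0, 15.0, 1.0)
        assert len(wins) == 46
        assert wins[0].end_time_s == 15.0
        assert wins[-1].end_time_s == 60.0
        assert wins[0].index == 1

    def test_trial_equal_to_window_is_single(self):
        assert len(enumerate_windows(15.0, 15.0, 1.0)) == 1

    def test_short_trial_raises(self):
        with pytest.raises(ParameterError):
            enumerate_windows(14.5, 15.0, 1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        duration=st.integers(15, 120),
        window=st.integers(5, 15),
        step=st.sampled_from([1, 2, 5]),
    )
    def test_count_and_end_times_formula(self, duration, window, step):
        wins = enumerate_windows(float(duration), float(window), float(step),
                                 buffer_s=float(window))
        assert len(wins) == int((duration - window) // step) + 1
        for i, w in enumerate(wins):
            assert w.end_time_s == window + i * step
            assert w.end_time_s <= duration
            a, b = w.sample_range(64.0)
            assert b - a == window * 64


class TestEMA:
    def test_hand_evaluated_recursion(self):
        np.testing.assert_allclose(apply_ema([1.0, 0.0, 0.0], 0.1),
                                   [1.0, 0.9, 0.81])

    def test_alpha_one_is_identity(self, rng):
        x = rng.standard_normal(20)
        np.testing.assert_array_equal(apply_ema(x, 1.0), x)

    def test_constant_is_fixed_point(self):
        np.testing.assert_allclose(apply_ema(np.full(30, 0.42), 0.1), 0.42)

    def test_invalid_alpha_raises(self):
        for alpha in (0.0, -0.5, 1.5):
            with pytest.raises(ParameterError):
                apply_ema([1.0], alpha)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 50),
           alpha=st.floats(0.05, 1.0),
           k=st.integers(10, 60))
    def test_smoothing_never_amplifies(self, seed, alpha, k):
        x = np.random.default_rng(seed).standard_normal(k)
        y = apply_ema(x, alpha)
        assert np.abs(y).max() <= np.abs(x).max() + 1e-12
        assert y.var() <= x.var() + 1e-12


class TestSnippetDecoder:
    def test_matches_bruteforce_oracle(self, rng, cfg):
        from aadkit.preprocessing import Snippet
        eeg = zscore(rng.standard_normal((2, 960)))
        seg = zscore(rng.standard_normal(960))
        snip = Snippet(eeg=eeg, envelope_segments=(seg,), window_index=1,
                       window_end_s=15.0, fs_proc=64.0)
        lags = np.array([0, 1, 2])
        from aadkit.realtime_decoder import _fit_snippet
        dec = _fit_snippet(snip, seg, 10.0, lags)
        R = np.zeros((6, 960))
        for k, tau in enumerate(lags):
            R[2 * k:2 * k + 2, :960 - tau] = eeg[:, tau:]
        w = ridge_oracle(R, seg, 10.0)
        np.testing.assert_allclose(dec.weights.ravel(), w, rtol=1e-8,
                                   atol=1e-10)

    def test_noiseless_snippet_reconstructs_itself(self):
        cfg, ds = small_dataset(seed=4, noise_sd=0.0, n_fixed=2,
                                n_switching=0, duration_s=20.0)
        eeg, envs, meta = ds.trials[0]
        from aadkit.preprocessing import preprocess_snippet
        buf = eeg.data[:, : int(15 * 125)]
        snip = preprocess_snippet(buf, envs, cfg, 1, 15.0, eeg.channel_labels)
        att = snip.envelope_segments[meta.attended_speaker - 1]
        dec = fit_snippet_decoder(snip, att, cfg.lambda_reg)
        from aadkit.offline_decoder import build_lagged_design, \
            reconstruct_envelope
        trial = ak.EEGTrial(snip.eeg, 64.0, eeg.channel_labels,
                            reference="common-average")
        design = build_lagged_design(trial, dec.lag_samples)
        s_hat = reconstruct_envelope(dec, design).values
        assert pearson(s_hat, att) > 0.99


@pytest.fixture(scope="module")
def trained():
    cfg, ds = small_dataset(seed=5, noise_sd=0.0, n_fixed=3,
                            n_switching=1, duration_s=20.0)
    rt = train_realtime_decoder(ds.fixed()[:2], cfg)
    return cfg, ds, rt


class TestTrainingAndStreaming:
    def test_provenance_counts_all_snippets(self, trained):
        cfg, ds, rt = trained
        # 2 trials x 6 windows of a 20-s trial at W=15, M=1
        assert rt.provenance == 12

    def test_empty_training_set_raises(self, cfg):
        with pytest.raises(ParameterError):
            train_realtime_decoder([], cfg)

    def test_noise_free_decisions_all_correct(self, trained):
        cfg, ds, rt = trained
        eeg, envs, meta = ds.fixed()[2]
        trace = stream_decode(eeg, envs, meta, rt, cfg)
        assert np.all(trace.decisions == meta.attended_speaker)
        assert np.all(trace.correct)

    def test_relabeled_metadata_flips_correctness(self, trained):
        cfg, ds, rt = trained
        eeg, envs, meta = ds.fixed()[2]
        flipped = ak.TrialMetadata(meta.trial_id, 3 - meta.attended_speaker,
                                   meta.attended_side_initial, meta.kind,
                                   meta.duration_s, meta.switch_time_s)
        trace = stream_decode(eeg, envs, flipped, rt, cfg)
        assert not trace.correct.any()

    def test_ema_trace_satisfies_recursion(self, trained):
        cfg, ds, rt = trained
        eeg, envs, meta = ds.fixed()[2]
        trace = stream_decode(eeg, envs, meta, rt, cfg)
        np.testing.assert_allclose(trace.r1_ema,
                                   apply_ema(trace.r1_raw, cfg.ema_alpha),
                                   atol=1e-12)
        np.testing.assert_allclose(trace.r2_ema,
                                   apply_ema(trace.r2_raw, cfg.ema_alpha),
                                   atol=1e-12)

    def test_alpha_one_matches_raw_decisions(self, trained):
        from dataclasses import replace
        cfg, ds, rt = trained
        eeg, envs, meta = ds.fixed()[2]
        cfg1 = replace(cfg, ema_alpha=1.0)
        trace = stream_decode(eeg, envs, meta, rt, cfg1)
        raw_dec = np.where(trace.r1_raw > trace.r2_raw, 1, 2)
        np.testing.assert_array_equal(trace.decisions, raw_dec)

    def test_streaming_is_reproducible(self, trained):
        cfg, ds, rt = trained
        eeg, envs, meta = ds.fixed()[2]
        a = stream_decode(eeg, envs, meta, rt, cfg)
        b = stream_decode(eeg, envs, meta, rt, cfg)
        np.testing.assert_array_equal(a.r1_raw, b.r1_raw)
        np.testing.assert_array_equal(a.decisions, b.decisions)

    def test_window_bookkeeping_matches_enumeration(self, trained):
        cfg, ds, rt = trained
        eeg, envs, meta = ds.fixed()[0]
        trace = stream_decode(eeg, envs, meta, rt, cfg)
        wins = enumerate_windows(meta.duration_s, cfg.window_s, cfg.step_s)
        np.testing.assert_array_equal(trace.window_end_s,
                                      [w.end_time_s for w in wins])


class TestWindowAccuracy:
    @staticmethod
    def _trace(correct, kind="fixed", trial_id="t"):
        n = len(correct)
        meta = ak.TrialMetadata(trial_id, 1, "left", kind, 60.0,
                                switch_time_s=30.0 if kind == "switching"
                                else None)
        z = np.zeros(n)
        return ak.CorrelationTrace(
            trial_id=trial_id, window_indices=np.arange(1, n + 1),
            window_end_s=np.arange(15.0, 15.0 + n), r1_raw=z, r2_raw=z,
            r1_ema=z, r2_ema=z, decisions=np.ones(n, dtype=int),
            correct=np.asarray(correct, dtype=bool), ema_alpha=0.1,
            metadata=meta)

    def test_half_correct_is_50(self):
        acc = window_accuracy([self._trace([True] * 23 + [False] * 23)])
        assert acc["all_pct"] == 50.0

    def test_all_wrong_is_0(self):
        assert window_accuracy([self._trace([False] * 10)])["all_pct"] == 0.0

    def test_split_by_kind(self):
        traces = [self._trace([True] * 4, "fixed", "a"),
                  self._trace([False] * 4, "switching", "b")]
        acc = window_accuracy(traces)
        assert acc["fixed_pct"] == 100.0
        assert acc["switching_pct"] == 0.0
        assert acc["all_pct"] == 50.0

    def test_empty_raises(self):
        with pytest.raises(ParameterError):
            window_accuracy([])
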