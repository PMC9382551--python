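"""Signal tier: windowing, noise screen, R-peak detection, CBD, IBIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nextstress as ns
from nextstress.ecg import (EcgRecording, NOISE_FRACTION_MAX, apply_ibi_range,
                            assess_noise, cbd_filter, compute_ibis,
                            detect_r_peaks, fit_noise_ensemble,
                            merge_window_peaks, second_reliability,
                            segment_windows)
from nextstress.synthetic import EcgGenConfig, StateTrack, render_ecg


def _recording(duration_s, rate=250.0):
    n = int(duration_s * rate)
    t = np.arange(n) / rate * 1000.0
    return EcgRecording("t", t, np.zeros(n), rate)


class TestWindowing:
    @pytest.mark.parametrize("duration_s,expected", [(300, 9), (60, 1), (59, 0)])
    def test_window_counts(self, duration_s, expected):
        assert len(segment_windows(_recording(duration_s))) == expected

    def test_windows_are_60s_stepping_30s(self):
        grid = segment_windows(_recording(200))
        for (a, b) in grid.windows:
            assert b - a == 60_000.0
        starts = [w[0] for w in grid.windows]
        assert np.allclose(np.diff(starts), 30_000.0)


class TestReliability:
    def test_boundary_is_strict(self):
        rate = 250.0
        # one second with exactly 200 of 250 points -> r = 0.80, discarded
        t = np.concatenate([np.linspace(0, 999, 200),
                            np.linspace(1000, 1999, 250)])
        rec = EcgRecording("t", t, np.zeros(t.size), rate)
        r = second_reliability(rec)
        assert r[0] == pytest.approx(0.80)
        assert not (r[0] > 0.80)
        assert r[1] > 0.80


class _FixedEnsemble:
    """Stub flagging the first k intervals of each window as noisy."""

    fitted = True

    def __init__(self, k):
        self.k = k
        self.n_seen = 0

    def predict_noisy(self, X):
        out = np.zeros(len(X), dtype=bool)
        out[:self.k] = True
        return out


class TestNoiseScreen:
    @pytest.mark.parametrize("k,retained", [(13, True), (20, True), (21, False)])
    def test_twenty_percent_boundary(self, k, retained):
        rec = _recording(60)
        grid = segment_windows(rec)
        na = assess_noise(rec, grid, _FixedEnsemble(k))
        assert len(grid) == 1 and na.noisy_fraction[0] == pytest.approx(k / 100)
        assert bool(na.window_retained[0]) is retained

    def test_retention_monotone_in_threshold(self):
        fractions = np.array([0.0, 0.1, 0.19, 0.21, 0.5, 1.0])
        kept = [np.sum(fractions <= t) for t in (0.05, 0.20, 0.50)]
        assert kept == sorted(kept)

    def test_unfitted_ensemble_signals(self):
        ens = ns.ecg.NoiseEnsemble()
        rec = _recording(60)
        with pytest.raises(RuntimeError):
            assess_noise(rec, segment_windows(rec), ens)

    def test_single_class_training_rejected(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        with pytest.raises(ValueError):
            fit_noise_ensemble(X, np.ones(50))


@pytest.fixture(scope="module")
def fitted():
    X, y = ns.pipeline.noise_training_set(21)
    return fit_noise_ensemble(X, y, seed=0)


class TestNoiseEnsemble:
    def test_holdout_accuracy(self, fitted):
        X2, y2 = ns.pipeline.noise_training_set(22)
        acc = np.mean(fitted.predict_noisy(X2) == y2.astype(bool))
        assert acc >= 0.90

    def test_all_noise_called_noisy(self, fitted):
        X2, y2 = ns.pipeline.noise_training_set(23)
        noisy_only = X2[y2 == 1]
        assert fitted.predict_noisy(noisy_only).mean() >= 0.9

    def test_deterministic_predictions(self, fitted):
        X2, _ = ns.pipeline.noise_training_set(24)
        a = fitted.predict_noisy(X2)
        b = fitted.predict_noisy(X2)
        np.testing.assert_array_equal(a, b)


class TestRPeaks:
    def test_clean_minute_at_60bpm(self):
        cfg = EcgGenConfig(calm_ibi_mean=1000.0, calm_ibi_sd=20.0,
                           noise_segment_fraction=0.0, dropout_fraction=0.0)
        track = StateTrack("", np.zeros(1, dtype=bool), 0.0, 1.0)
        day = render_ecg(track, cfg, np.random.default_rng(11))
        times, amps, proms = detect_r_peaks(day.voltage, cfg.sampling_rate)
        assert abs(times.size - day.beat_times_ms.size) <= 1
        tp, fp, fn, errs = ns.pipeline.match_peaks(times, day.beat_times_ms,
                                                   tol_ms=10.0)
        assert fn <= 1 and fp <= 1
        assert np.all(errs <= 10.0)

    def test_all_zero_signal_yields_no_peaks(self):
        times, _, _ = detect_r_peaks(np.zeros(15000), 250.0)
        assert times.size == 0


class TestCbd:
    def test_regular_series_unchanged(self):
        peaks = np.arange(0, 60_000, 1000.0)
        np.testing.assert_array_equal(cbd_filter(peaks), peaks)

    def test_spurious_beat_removed(self):
        peaks = list(np.arange(0, 60_000, 1000.0))
        peaks.append(30_250.0)  # splits one 1000 ms IBI into 250 + 750
        filtered = cbd_filter(np.sort(peaks))
        assert 30_250.0 not in filtered
        assert np.allclose(np.diff(filtered), 1000.0)

    def test_long_gap_excluded_by_range_rule(self):
        peaks = np.concatenate([np.arange(0, 10_000, 1000.0),
                                np.arange(12_500, 20_000, 1000.0)])
        ibis = apply_ibi_range(compute_ibis(cbd_filter(peaks)))
        assert (ibis["ibi_ms"] <= 2000).all()
        assert 2500.0 not in ibis["ibi_ms"].to_numpy()

    def test_passthrough_below_three_peaks(self):
        peaks = np.array([0.0, 800.0])
        np.testing.assert_array_equal(cbd_filter(peaks), peaks)


class TestIbis:
    def test_examples(self):
        out = compute_ibis(np.array([0.0, 1000.0, 2000.0]))
        assert out["ibi_ms"].tolist() == [1000.0, 1000.0]
        assert compute_ibis(np.array([500.0])).empty

    @given(st.lists(st.floats(1, 2000), min_size=2, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_sum_telescopes_to_span(self, gaps):
        peaks = np.cumsum(np.asarray(gaps))
        out = compute_ibis(peaks)
        assert out["ibi_ms"].sum() == pytest.approx(peaks[-1] - peaks[0])


class TestOverlapMerge:
    def test_duplicate_within_tolerance_appears_once(self):
        w1 = (np.array([1000.0, 2000.0]), np.ones(2), np.ones(2))
        w2 = (np.array([2008.0, 3000.0]), np.ones(2), np.ones(2))
        times, _, _ = merge_window_peaks([w1, w2], tol_ms=20.0)
        assert times.tolist() == [1000.0, 2000.0, 3000.0]


class TestPipelineOracle:
    def test_zero_noise_ibi_error_below_8ms(self):
        res = ns.pipeline.ibi_pipeline_benchmark(2, 10, seed=31,
                                                 noise_fraction=0.0)
        assert res["median_abs_error_ms"] <= 8.0
        assert res["n_ibis_scored"] > 500

    def test_clean_fraction_bookkeeping(self):
        X, y = ns.pipeline.noise_training_set(25)
        ens = fit_noise_ensemble(X, y, seed=0)
        cfg = EcgGenConfig(noise_segment_fraction=0.3, dropout_fraction=0.0)
        track = StateTrack("", np.zeros(10, dtype=bool), 0.0, 1.0)
        day = render_ecg(track, cfg, np.random.default_rng(32))
        rec = EcgRecording("q", day.t_ms, day.voltage, cfg.sampling_rate)
        _, _, report = ns.ecg.process_recording(rec, ens)
        assert 0 <= report.windows_retained <= report.windows_total
        assert report.clean_pct == pytest.approx(
            100.0 * report.windows_retained / report.windows_total)
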