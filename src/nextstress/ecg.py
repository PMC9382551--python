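"""Raw-ECG to quality-screened interbeat intervals.

The pipeline mirrors a patch-sensor workflow: overlapping one-minute
windows, a two-classifier noise screen over 0.6-s intervals, a per-second
sampling-reliability check, Shannon-energy R-peak detection, and a
criterion-beat-difference (CBD) artifact filter before IBIs are emitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

log = logging.getLogger(__name__)

WINDOW_S = 60.0
STEP_S = 30.0
NOISE_INTERVAL_S = 0.6
NOISE_FRACTION_MAX = 0.20   # windows with > 20% noisy intervals are discarded
RELIABILITY_MIN = 0.80      # seconds with reliability <= 80% are discarded
IBI_RANGE_MS = (300.0, 2000.0)  # plausible human heart-rhythm range
DEDUP_TOL_MS = 20.0
REFRACTORY_S = 0.25


@dataclass
class EcgRecording:
    participant_day_id: str
    t_ms: np.ndarray
    voltage: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be positive")
        if self.t_ms.size > 1 and np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def duration_ms(self) -> float:
        if self.t_ms.size == 0:
            return 0.0
        return float(self.t_ms[-1] - self.t_ms[0]) + 1000.0 / self.nominal_rate


@dataclass
class WindowGrid:
    windows: list  # of (start_ms, end_ms), each exactly 60 s, stepping 30 s

    def __len__(self) -> int:
        return len(self.windows)


@dataclass
class NoiseAssessment:
    noisy_fraction: np.ndarray      # per window
    window_retained: np.ndarray     # bool per window
    second_reliability: np.ndarray  # per second of the recording span
    second_ok: np.ndarray           # bool, reliability strictly > 0.80


@dataclass
class QualityReport:
    windows_total: int
    windows_retained: int

    @property
    def clean_pct(self) -> float:
        if self.windows_total == 0:
            return float("nan")
        return 100.0 * self.windows_retained / self.windows_total


def segment_windows(rec: EcgRecording, window_s: float = WINDOW_S,
                    step_s: float = STEP_S) -> WindowGrid:
    """One-minute windows with 30-s overlap; last window fully inside."""
    dur_ms = rec.duration_ms
    win_ms, step_ms = window_s * 1000.0, step_s * 1000.0
    if dur_ms < win_ms:
        log.warning("recording %s shorter than one window (%.1f s)",
                    rec.participant_day_id, dur_ms / 1000.0)
        return WindowGrid([])
    t0 = float(rec.t_ms[0])
    n = int(np.floor((dur_ms - win_ms) / step_ms)) + 1
    return WindowGrid([(t0 + i * step_ms, t0 + i * step_ms + win_ms)
                       for i in range(n)])


def second_reliability(rec: EcgRecording) -> np.ndarray:
    """Observed points per second divided by the nominal rate."""
    if rec.t_ms.size == 0:
        return np.zeros(0)
    t0 = rec.t_ms[0]
    n_sec = int(np.ceil(rec.duration_ms / 1000.0))
    sec = np.clip(((rec.t_ms - t0) // 1000).astype(int), 0, n_sec - 1)
    counts = np.bincount(sec, minlength=n_sec)
    return counts / rec.nominal_rate


def interval_noise_features(v: np.ndarray, rate: float) -> np.ndarray:
    """Three beat-derived screening features for one 0.6-s interval.

    1. detected-peak count (prominence-gated local maxima),
    2. coefficient of variation of detected peak amplitudes,
    3. high-frequency (>15 Hz) energy ratio.
    Broadband sensor noise inflates all three relative to clean ECG.
    """
    v = np.asarray(v, dtype=float)
    if v.size < 8:
        return np.array([0.0, 0.0, 0.0])
    vc = v - np.median(v)
    mad = np.median(np.abs(vc)) + 1e-12
    pk, props = signal.find_peaks(vc, prominence=3.0 * mad)
    amps = vc[pk]
    cv = float(np.std(amps) / (np.abs(np.mean(amps)) + 1e-12)) if amps.size >= 2 else 0.0
    spec = np.abs(np.fft.rfft(vc)) ** 2
    freqs = np.fft.rfftfreq(vc.size, d=1.0 / rate)
    total = spec.sum() + 1e-12
    hf = spec[freqs > 15.0].sum() / total
    return np.array([float(pk.size), min(cv, 10.0), float(hf)])


def _intervals_of_window(v: np.ndarray, rate: float,
                         interval_s: float = NOISE_INTERVAL_S) -> list:
    n = int(round(interval_s * rate))
    return [v[i:i + n] for i in range(0, len(v) - n + 1, n)]


class NoiseEnsemble:
    """Margin-based + feedforward interval classifiers with a conservative
    agreement rule: an interval is called clean only when both agree."""

    def __init__(self, seed: int = 0):
        from sklearn.neural_network import MLPClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        self._svm = make_pipeline(StandardScaler(), SVC(C=1.0, kernel="rbf"))
        self._net = make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(16,), max_iter=800,
                          random_state=seed))
        self.fitted = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NoiseEnsemble":
        y = np.asarray(y).astype(int)  # 1 = noisy
        if np.unique(y).size < 2:
            raise ValueError("noise-ensemble training needs both classes")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._svm.fit(X, y)
            self._net.fit(X, y)
        self.fitted = True
        return self

    def predict_noisy(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("noise ensemble is not fitted")
        a = self._svm.predict(X).astype(bool)
        b = self._net.predict(X).astype(bool)
        return a | b  # noisy unless both agree clean


def fit_noise_ensemble(features: np.ndarray, labels: np.ndarray,
                       seed: int = 0) -> NoiseEnsemble:
    return NoiseEnsemble(seed=seed).fit(np.asarray(features), labels)


def assess_noise(rec: EcgRecording, grid: WindowGrid,
                 ensemble: NoiseEnsemble) -> NoiseAssessment:
    """Score each window's 0.6-s intervals and each second's reliability."""
    if not ensemble.fitted:
        raise RuntimeError("noise ensemble is not fitted")
    rel = second_reliability(rec)
    sec_ok = rel > RELIABILITY_MIN
    fractions = np.zeros(len(grid))
    retained = np.zeros(len(grid), dtype=bool)
    t0 = rec.t_ms[0] if rec.t_ms.size else 0.0
    for w, (a, b) in enumerate(grid.windows):
        lo = np.searchsorted(rec.t_ms, a)
        hi = np.searchsorted(rec.t_ms, b)
        v = rec.voltage[lo:hi]
        ivs = _intervals_of_window(v, rec.nominal_rate)
        if not ivs:
            fractions[w] = 1.0
            continue
        feats = np.array([interval_noise_features(iv, rec.nominal_rate)
                          for iv in ivs])
        noisy = ensemble.predict_noisy(feats)
        fractions[w] = noisy.mean()
        retained[w] = fractions[w] <= NOISE_FRACTION_MAX
    return NoiseAssessment(fractions, retained, rel, sec_ok)


def shannon_envelope(v: np.ndarray, rate: float,
                     band=(5.0, 25.0), diff_sigma_s: float = 0.010,
                     smooth_sigma_s: float = 0.040) -> np.ndarray:
    """Band-pass -> first-order Gaussian differentiator -> squaring ->
    Shannon energy -s^2 log s^2 -> Gaussian smoothing."""
    sos = signal.butter(2, band, btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, v)
    d = gaussian_filter1d(x, sigma=diff_sigma_s * rate, order=1)
    s2 = d ** 2
    peak = s2.max()
    if peak <= 0:
        return np.zeros_like(v)
    s2 = s2 / peak
    with np.errstate(divide="ignore", invalid="ignore"):
        se = -s2 * np.log(s2)
    se[~np.isfinite(se)] = 0.0
    return gaussian_filter1d(se, sigma=smooth_sigma_s * rate)


def detect_r_peaks(v: np.ndarray, rate: float, t0_ms: float = 0.0,
                   refractory_s: float = REFRACTORY_S):
    """Shannon-energy R-peak detection on one clean window.

    Returns (times_ms, amplitudes, prominences). Peak times are refined
    to the nearest extremum of the band-passed signal within +/-50 ms.
    """
    v = np.asarray(v, dtype=float)
    if v.size < int(0.5 * rate) or np.allclose(v, v[0] if v.size else 0.0):
        return np.zeros(0), np.zeros(0), np.zeros(0)
    env = shannon_envelope(v, rate)
    if env.max() <= 0:
        return np.zeros(0), np.zeros(0), np.zeros(0)
    height = 0.18 * np.percentile(env, 99.5)
    locs, props = signal.find_peaks(env, height=height,
                                    distance=max(1, int(refractory_s * rate)))
    if locs.size == 0:
        return np.zeros(0), np.zeros(0), np.zeros(0)
    sos = signal.butter(2, (5.0, 25.0), btype="bandpass", fs=rate, output="sos")
    xf = signal.sosfiltfilt(sos, v)
    half = int(0.05 * rate)
    refined = np.empty(locs.size, dtype=int)
    for i, l in enumerate(locs):
        lo, hi = max(0, l - half), min(v.size, l + half + 1)
        seg = xf[lo:hi]
        refined[i] = lo + int(np.argmax(np.abs(seg)))
    refined = np.unique(refined)
    amps = np.abs(xf[refined])
    proms = signal.peak_prominences(np.abs(xf), refined)[0]
    times = t0_ms + refined / rate * 1000.0
    return times, amps, proms


def merge_window_peaks(per_window: list, tol_ms: float = DEDUP_TOL_MS):
    """Merge peak lists from overlapping windows, deduplicating within tol."""
    if not per_window:
        return np.zeros(0), np.zeros(0), np.zeros(0)
    times = np.concatenate([p[0] for p in per_window])
    amps = np.concatenate([p[1] for p in per_window])
    proms = np.concatenate([p[2] for p in per_window])
    order = np.argsort(times)
    times, amps, proms = times[order], amps[order], proms[order]
    keep_t, keep_a, keep_p = [], [], []
    for t, a, p in zip(times, amps, proms):
        if keep_t and t - keep_t[-1] <= tol_ms:
            continue
        keep_t.append(t); keep_a.append(a); keep_p.append(p)
    return np.array(keep_t), np.array(keep_a), np.array(keep_p)


def cbd_filter(peak_times_ms: np.ndarray, window: int = 51,
               max_iter: int = 20) -> np.ndarray:
    """Criterion-beat-difference artifact rejection.

    From the running IBI distribution: quartile deviation QD, maximal
    expected difference MED = 3.32*QD, minimal artifact difference
    MAD = (median IBI - 2.9*QD)/3, criterion = (MED + MAD)/2. A beat both
    of whose adjacent IBIs deviate from the running median by more than
    the criterion is removed (an inserted spurious beat splits one
    plausible interval into two implausible ones); removal iterates to
    a fixed point.
    """
    peaks = np.asarray(peak_times_ms, dtype=float)
    if peaks.size < 3:
        if peaks.size:
            log.warning("cbd_filter: fewer than 3 peaks, passing through")
        return peaks
    for _ in range(max_iter):
        ibis = np.diff(peaks)
        s = pd.Series(ibis)
        roll = s.rolling(window, center=True, min_periods=3)
        med = roll.median().to_numpy()
        qd = ((roll.quantile(0.75) - roll.quantile(0.25)) / 2.0).to_numpy()
        med = np.where(np.isfinite(med), med, np.median(ibis))
        qd = np.where(np.isfinite(qd), qd, 0.0)
        crit = (3.32 * qd + (med - 2.9 * qd) / 3.0) / 2.0
        crit = np.maximum(crit, 1.0)
        dev = np.abs(ibis - med) > crit
        # beat i sits between ibis[i-1] and ibis[i]
        bad_beats = np.flatnonzero(dev[:-1] & dev[1:]) + 1
        if bad_beats.size == 0:
            break
        # drop non-adjacent offenders only, then re-evaluate
        selected = [bad_beats[0]]
        for b in bad_beats[1:]:
            if b > selected[-1] + 1:
                selected.append(b)
        peaks = np.delete(peaks, selected)
        if peaks.size < 3:
            break
    return peaks


def compute_ibis(peak_times_ms: np.ndarray) -> pd.DataFrame:
    """IBIs between consecutive beats; onset is the earlier beat's time."""
    peaks = np.asarray(peak_times_ms, dtype=float)
    if peaks.size < 2:
        return pd.DataFrame(columns=["onset_ms", "ibi_ms"])
    return pd.DataFrame({"onset_ms": peaks[:-1], "ibi_ms": np.diff(peaks)})


def apply_ibi_range(ibis: pd.DataFrame,
                    ibi_range=IBI_RANGE_MS) -> pd.DataFrame:
    """Drop intervals outside the plausible human heart-rhythm range."""
    lo, hi = ibi_range
    ok = (ibis["ibi_ms"] >= lo) & (ibis["ibi_ms"] <= hi)
    return ibis.loc[ok].reset_index(drop=True)


def process_recording(rec: EcgRecording, ensemble: NoiseEnsemble):
    """Full Figure-3-style pipeline for one recording.

    Returns (ibis DataFrame with onset_ms/ibi_ms, peak-feature DataFrame
    with peak times/amplitudes/prominences, QualityReport).
    """
    grid = segment_windows(rec)
    if len(grid) == 0:
        return (pd.DataFrame(columns=["onset_ms", "ibi_ms"]),
                pd.DataFrame(columns=["time_ms", "amplitude", "prominence"]),
                QualityReport(0, 0))
    na = assess_noise(rec, grid, ensemble)
    t0 = rec.t_ms[0]
    per_window = []
    for w, (a, b) in enumerate(grid.windows):
        if not na.window_retained[w]:
            continue
        lo = np.searchsorted(rec.t_ms, a)
        hi = np.searchsorted(rec.t_ms, b)
        if hi - lo < int(0.9 * WINDOW_S * rec.nominal_rate):
            continue  # dropout inside the window
        secs = ((rec.t_ms[lo:hi] - t0) // 1000).astype(int)
        ok = na.second_ok[np.clip(secs, 0, na.second_ok.size - 1)]
        if not ok.all():
            continue
        per_window.append(detect_r_peaks(rec.voltage[lo:hi],
                                         rec.nominal_rate, t0_ms=a))
    times, amps, proms = merge_window_peaks(per_window)
    times_f = cbd_filter(times)
    kept = np.isin(times, times_f)
    peaks = pd.DataFrame({"time_ms": times_f, "amplitude": amps[kept],
                          "prominence": proms[kept]})
    ibis = apply_ibi_range(compute_ibis(times_f))
    report = QualityReport(len(grid), int(na.window_retained.sum()))
    return ibis, peaks, report
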