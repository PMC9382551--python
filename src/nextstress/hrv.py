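"""Minute-level heart-rate-variability features.

Thirty named statistics per minute of interbeat intervals: 15 time-domain,
7 frequency-domain (Lomb-Scargle on the unevenly sampled IBI series, so no
resampling is needed), 4 Poincare/entropy, and 4 R-peak-derived. A minute
needs at least two IBIs to be valid; invalid minutes come back all-NaN and
are excluded from day-level means.

Everything is computed on a NaN-padded (minutes x beats) matrix so that a
full study's minutes can be processed in vectorized chunks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TIME_FEATURES = [
    "mean_ibi", "median_ibi", "min_ibi", "max_ibi", "sdnn", "rmssd", "sdsd",
    "pnn50", "pnn20", "cvnn", "mean_hr", "min_hr", "max_hr", "hr_range",
    "triangular_index",
]
FREQ_FEATURES = [
    "vlf_power", "lf_power", "hf_power", "total_power", "lf_hf_ratio",
    "lf_norm", "hf_norm",
]
NONLINEAR_FEATURES = ["sd1", "sd2", "sd1_sd2_ratio", "sample_entropy"]
PEAK_FEATURES = [
    "peak_count", "peak_amp_mean", "peak_amp_sd", "peak_prominence_mean",
]
HRV_FEATURES = TIME_FEATURES + FREQ_FEATURES + NONLINEAR_FEATURES + PEAK_FEATURES
assert len(HRV_FEATURES) == 30

VLF_BAND = (0.0033, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
_FREQS = np.arange(0.004, 0.444, 0.008)  # Hz, covers VLF/LF/HF
_TRI_BIN_MS = 1000.0 / 128.0  # standard 7.8125 ms histogram bin


def _pad(arrs: list) -> np.ndarray:
    m = max((len(a) for a in arrs), default=0)
    out = np.full((len(arrs), max(m, 1)), np.nan)
    for i, a in enumerate(arrs):
        out[i, :len(a)] = a
    return out


def _lomb_band_powers(X: np.ndarray, valid: np.ndarray) -> dict:
    """Vectorized Lomb-Scargle band powers for each row of IBIs (ms)."""
    t = np.where(valid, np.nancumsum(np.where(valid, X, 0.0), axis=1), np.nan) / 1000.0
    n = valid.sum(axis=1, keepdims=True).astype(float)
    mean = np.nansum(np.where(valid, X, 0.0), axis=1, keepdims=True) / np.maximum(n, 1)
    x = np.where(valid, X - mean, 0.0)
    tz = np.where(valid, t, 0.0)
    w = valid.astype(float)
    P = np.zeros((X.shape[0], _FREQS.size))
    for k, f in enumerate(_FREQS):
        om = 2.0 * np.pi * f
        s2 = np.sum(w * np.sin(2 * om * tz), axis=1)
        c2 = np.sum(w * np.cos(2 * om * tz), axis=1)
        tau = np.arctan2(s2, c2) / (2.0 * om)
        arg = om * (tz - tau[:, None])
        ct, st = np.cos(arg) * w, np.sin(arg) * w
        num_c = np.sum(x * ct, axis=1) ** 2
        num_s = np.sum(x * st, axis=1) ** 2
        den_c = np.sum(ct ** 2, axis=1)
        den_s = np.sum(st ** 2, axis=1)
        P[:, k] = 0.5 * (num_c / np.maximum(den_c, 1e-12)
                         + num_s / np.maximum(den_s, 1e-12))
    df = _FREQS[1] - _FREQS[0]
    out = {}
    for name, (lo, hi) in (("vlf_power", VLF_BAND), ("lf_power", LF_BAND),
                           ("hf_power", HF_BAND)):
        sel = (_FREQS >= lo) & (_FREQS < hi)
        out[name] = P[:, sel].sum(axis=1) * df
    return out


def _sample_entropy(X: np.ndarray, valid: np.ndarray, sdnn: np.ndarray,
                    m: int = 2) -> np.ndarray:
    """Sample entropy (m=2, r=0.2*SDNN, Chebyshev), with a +1 continuity
    guard in both counts so short or perfectly regular minutes stay finite
    (constant series -> 0)."""
    # padded entries get distinct large sentinels so no pair of them (nor
    # any real/padded pair) can ever fall within the tolerance r
    pad_vals = 1e9 * (np.arange(X.shape[1], dtype=np.float64) + 1.0)
    Z = np.where(valid, X, pad_vals[None, :]).astype(np.float32)
    sentinel = np.float32(3e38)
    r = (0.2 * np.where(np.isfinite(sdnn), sdnn, 0.0)).astype(np.float32)
    r = r[:, None, None]
    n = Z.shape[1]
    c = Z.shape[0]
    if n < m + 2:
        return np.zeros(c)
    D = np.abs(Z[:, :, None] - Z[:, None, :])
    np.minimum(D, sentinel, out=D)

    def _count(d: np.ndarray) -> np.ndarray:
        match = d <= r
        total = match.sum(axis=(1, 2)).astype(float)
        diag = np.trace(match, axis1=1, axis2=2).astype(float)
        return total - diag

    d2 = np.maximum(D[:, :n - 1, :n - 1], D[:, 1:, 1:])
    B = _count(d2)                                        # length-m templates
    d3 = np.maximum(d2[:, :n - 2, :n - 2], D[:, 2:, 2:])
    A = _count(d3)                                        # length-(m+1)
    return -np.log((A + 1.0) / (B + 1.0))


def _triangular_index(X: np.ndarray, valid: np.ndarray) -> np.ndarray:
    bins = np.where(valid, np.round(X / _TRI_BIN_MS), -1).astype(int)
    n_rows = X.shape[0]
    nbins = int(bins.max()) + 1 if bins.size else 1
    out = np.zeros(n_rows)
    counts = np.zeros((n_rows, max(nbins, 1)), dtype=np.int32)
    rows = np.repeat(np.arange(n_rows), X.shape[1])
    flat = bins.ravel()
    ok = flat >= 0
    np.add.at(counts, (rows[ok], flat[ok]), 1)
    modal = counts.max(axis=1)
    n = valid.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = n / np.maximum(modal, 1)
    return out


def hrv_matrix(ibi_list: list, amp_list: list | None = None,
               prom_list: list | None = None,
               chunk: int = 256) -> pd.DataFrame:
    """Compute the 30 HRV features for many minutes at once.

    ibi_list: per minute, an array of IBIs in ms (chronological).
    amp_list/prom_list: per minute, per-beat R-peak amplitudes and
    prominences (length = n_ibis + 1); default to 1.0 when absent.
    """
    n = len(ibi_list)
    out = np.full((n, 30), np.nan)
    if n == 0:
        return pd.DataFrame(out, columns=HRV_FEATURES)
    if amp_list is None:
        amp_list = [np.ones(len(x) + 1) for x in ibi_list]
    if prom_list is None:
        prom_list = amp_list
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        out[lo:hi] = _hrv_chunk(ibi_list[lo:hi], amp_list[lo:hi],
                                prom_list[lo:hi])
    return pd.DataFrame(out, columns=HRV_FEATURES)


def _hrv_chunk(ibi_list, amp_list, prom_list) -> np.ndarray:
    c = len(ibi_list)
    X = _pad([np.asarray(a, dtype=float) for a in ibi_list])
    valid = np.isfinite(X)
    nv = valid.sum(axis=1)
    ok = nv >= 2
    res = np.full((c, 30), np.nan)
    if not ok.any():
        return res
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_ibi = np.nanmean(X, axis=1)
        median_ibi = np.nanmedian(X, axis=1)
        min_ibi = np.nanmin(X, axis=1)
        max_ibi = np.nanmax(X, axis=1)
        sdnn = np.nanstd(X, axis=1, ddof=1)
        D = np.diff(X, axis=1)
        dvalid = np.isfinite(D)
        nd = dvalid.sum(axis=1)
        rmssd = np.sqrt(np.nanmean(D ** 2, axis=1))
        sdsd = np.where(nd >= 2, np.nanstd(D, axis=1, ddof=1), 0.0)
        absD = np.abs(D)
        pnn50 = 100.0 * np.nansum(absD > 50.0, axis=1) / np.maximum(nd, 1)
        pnn20 = 100.0 * np.nansum(absD > 20.0, axis=1) / np.maximum(nd, 1)
        cvnn = sdnn / mean_ibi
        hr = 60000.0 / X
        mean_hr = np.nanmean(hr, axis=1)
        min_hr = 60000.0 / max_ibi
        max_hr = 60000.0 / min_ibi
        hr_range = max_hr - min_hr
        tri = _triangular_index(X, valid)
        bands = _lomb_band_powers(X, valid)
        vlf, lf, hf = bands["vlf_power"], bands["lf_power"], bands["hf_power"]
        total = vlf + lf + hf
        lf_hf = np.where(hf > 1e-12, lf / np.maximum(hf, 1e-12), 0.0)
        denom = np.maximum(lf + hf, 1e-12)
        lf_norm = np.where(lf + hf > 1e-12, 100.0 * lf / denom, 0.0)
        hf_norm = np.where(lf + hf > 1e-12, 100.0 * hf / denom, 0.0)
        sd1 = np.sqrt(0.5) * np.where(nd >= 1, np.sqrt(np.nanmean(D ** 2, axis=1)), 0.0)
        sd2sq = 2.0 * sdnn ** 2 - 0.5 * sdsd ** 2
        sd2 = np.sqrt(np.maximum(sd2sq, 0.0))
        sd12 = np.where(sd2 > 1e-12, sd1 / np.maximum(sd2, 1e-12), 0.0)
        sampen = _sample_entropy(X, valid, sdnn)
        A = _pad([np.asarray(a, dtype=float) for a in amp_list])
        Pm = _pad([np.asarray(a, dtype=float) for a in prom_list])
        peak_count = np.isfinite(A).sum(axis=1).astype(float)
        amp_mean = np.nanmean(A, axis=1)
        amp_sd = np.where(peak_count >= 2, np.nanstd(A, axis=1, ddof=1), 0.0)
        prom_mean = np.nanmean(Pm, axis=1)
    cols = [mean_ibi, median_ibi, min_ibi, max_ibi, sdnn, rmssd, sdsd,
            pnn50, pnn20, cvnn, mean_hr, min_hr, max_hr, hr_range, tri,
            vlf, lf, hf, total, lf_hf, lf_norm, hf_norm,
            sd1, sd2, sd12, sampen,
            peak_count, amp_mean, amp_sd, prom_mean]
    stacked = np.column_stack(cols)
    res[ok] = stacked[ok]
    return res


def hrv_features_minute(ibis, amplitudes=None, prominences=None) -> pd.Series:
    """The 30-feature vector for a single minute (NaN if < 2 IBIs)."""
    row = hrv_matrix(
        [np.asarray(ibis, dtype=float)],
        None if amplitudes is None else [np.asarray(amplitudes, dtype=float)],
        None if prominences is None else [np.asarray(prominences, dtype=float)],
    )
    return row.iloc[0]
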