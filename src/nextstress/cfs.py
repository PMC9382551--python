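"""Correlation-based feature selection (Hall's CFS).

Subset merit for k features:
    merit(S) = k * r_cf / sqrt(k + k (k-1) * r_ff)
where r_cf is the mean feature-class correlation over S and r_ff the mean
feature-feature correlation. Correlation is symmetric uncertainty
SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y)) after equal-frequency discretization,
which handles mixed binary/continuous features on one scale. The search is
best-first over subsets, stopping after five consecutive non-improving
expansions.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

N_BINS = 5
STALE_LIMIT = 5


def discretize(x: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Equal-frequency binning; NaNs get their own bin."""
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, n_bins, dtype=int)  # NaN bin
    ok = np.isfinite(x)
    v = x[ok]
    if v.size == 0:
        return out
    qs = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    out[ok] = np.searchsorted(qs, v, side="right")
    return out


def symmetric_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """SU between two discrete (already binned) variables, in [0, 1]."""
    a = np.asarray(a)
    b = np.asarray(b)
    ab = a * (b.max() + 1) + b
    def _entropy(z):
        _, c = np.unique(z, return_counts=True)
        p = c / c.sum()
        return float(-(p * np.log(p)).sum())
    ha, hb = _entropy(a), _entropy(b)
    hab = _entropy(ab)
    mi = ha + hb - hab
    denom = ha + hb
    return 2.0 * mi / denom if denom > 1e-12 else 0.0


def merit(subset, su_cf: np.ndarray, su_ff: np.ndarray) -> float:
    idx = list(subset)
    k = len(idx)
    if k == 0:
        return 0.0
    rcf = float(np.mean(su_cf[idx]))
    if k == 1:
        return rcf
    sub = su_ff[np.ix_(idx, idx)]
    rff = float((sub.sum() - np.trace(sub)) / (k * (k - 1)))
    return k * rcf / np.sqrt(k + k * (k - 1) * rff)


@dataclass
class CfsResult:
    selected: list
    merit: float
    trace: list  # (subset tuple, merit) in visit order


def correlation_tables(X: np.ndarray, y: np.ndarray):
    """Precompute the SU(feature, class) vector and SU(feature, feature)
    matrix on discretized columns."""
    n, p = X.shape
    binned = np.column_stack([discretize(X[:, j]) for j in range(p)])
    yb = np.asarray(y).astype(int)
    su_cf = np.array([symmetric_uncertainty(binned[:, j], yb) for j in range(p)])
    su_ff = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            s = symmetric_uncertainty(binned[:, i], binned[:, j])
            su_ff[i, j] = su_ff[j, i] = s
    return su_cf, su_ff


def cfs_select(X: np.ndarray, y: np.ndarray,
               stale_limit: int = STALE_LIMIT) -> CfsResult:
    """Best-first search over feature subsets maximizing Hall's merit."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[1] < 2:
        raise ValueError("CFS needs at least two features")
    if np.unique(y).size < 2:
        raise ValueError("CFS needs a non-constant class")
    su_cf, su_ff = correlation_tables(X, y)
    if np.all(su_cf <= 1e-12):
        log.warning("all features uninformative; empty CFS selection")
        return CfsResult([], 0.0, [])
    p = X.shape[1]
    start = frozenset()
    best_subset, best_merit = start, 0.0
    visited = {start}
    trace = []
    # max-heap on merit via negation; tie-break on insertion order
    heap = [(-0.0, 0, start)]
    counter = 1
    stale = 0
    while heap and stale < stale_limit:
        _, _, subset = heapq.heappop(heap)
        improved = False
        for j in range(p):
            if j in subset:
                continue
            child = subset | {j}
            if child in visited:
                continue
            visited.add(child)
            m = merit(child, su_cf, su_ff)
            trace.append((tuple(sorted(child)), m))
            heapq.heappush(heap, (-m, counter, child))
            counter += 1
            if m > best_merit + 1e-12:
                best_subset, best_merit = child, m
                improved = True
        stale = 0 if improved else stale + 1
    return CfsResult(sorted(best_subset), best_merit, trace)


def exhaustive_cfs(X: np.ndarray, y: np.ndarray) -> CfsResult:
    """Brute-force merit optimum over all non-empty subsets (<= ~15 features)."""
    from itertools import combinations

    X = np.asarray(X, dtype=float)
    su_cf, su_ff = correlation_tables(X, y)
    p = X.shape[1]
    best, best_m = [], 0.0
    for k in range(1, p + 1):
        for combo in combinations(range(p), k):
            m = merit(combo, su_cf, su_ff)
            if m > best_m + 1e-12:
                best, best_m = list(combo), m
    return CfsResult(best, best_m, [])


def cfs_column_selector(feature_names=None):
    """Adapter: per-fold selector callable for ``cross_validate``."""
    def _select(X_tr, y_tr):
        res = cfs_select(X_tr, y_tr)
        return res.selected if res.selected else list(range(X_tr.shape[1]))
    return _select
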