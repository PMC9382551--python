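"""Gaussian-process Bayesian hyperparameter optimization.

The objective (mean 5-fold F1) is modeled as a Gaussian process over an
encoded hyperparameter space; candidates are scored by expected
improvement. Continuous dimensions are 200-value grids; categorical
dimensions enumerate all options. The default space targets the random
forest: n_estimators [10, 400], max_depth [2, 30], min_samples_split
[2, 40], criterion {gini, entropy}, max_features {sqrt, log2, None}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_GRID = 200


@dataclass
class Dimension:
    name: str
    values: list  # full grid (ints) or category list
    categorical: bool = False

    def encode(self, v) -> list:
        if self.categorical:
            return [1.0 if v == c else 0.0 for c in self.values]
        lo, hi = float(min(self.values)), float(max(self.values))
        return [(float(v) - lo) / (hi - lo) if hi > lo else 0.0]


def int_grid(lo: int, hi: int, n: int = N_GRID) -> list:
    return sorted(set(int(round(v)) for v in np.linspace(lo, hi, n)))


def default_rf_space() -> list:
    return [
        Dimension("n_estimators", int_grid(10, 400)),
        Dimension("max_depth", int_grid(2, 30)),
        Dimension("min_samples_split", int_grid(2, 40)),
        Dimension("criterion", ["gini", "entropy"], categorical=True),
        Dimension("max_features", ["sqrt", "log2", None], categorical=True),
    ]


@dataclass
class BoResult:
    best_params: dict
    best_score: float
    trace: pd.DataFrame  # one row per evaluation: params, score, incumbent
    space: list = field(default_factory=list)


def _sample_params(space, rng) -> dict:
    return {d.name: d.values[int(rng.integers(len(d.values)))] for d in space}


def _encode(space, params) -> np.ndarray:
    out = []
    for d in space:
        out.extend(d.encode(params[d.name]))
    return np.asarray(out)


def bayes_optimize(objective, space, n_iter: int = 40, n_init: int = 10,
                   seed: int = 0, n_candidates: int = 512) -> BoResult:
    """Maximize ``objective(params dict) -> float`` over the space.

    ``n_init`` random evaluations seed the surrogate; the remaining
    iterations fit a Matern-5/2 GP and evaluate the expected-improvement
    argmax over a random candidate pool drawn from the grid.
    """
    from scipy.stats import norm
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    total_points = int(np.prod([len(d.values) for d in space]))
    rng = np.random.default_rng(seed)
    evaluated: dict[tuple, float] = {}
    trace_rows = []
    X_obs, y_obs = [], []

    def evaluate(params: dict) -> float:
        key = tuple(params[d.name] for d in space)
        if key in evaluated:
            return evaluated[key]
        score = float(objective(params))
        evaluated[key] = score
        X_obs.append(_encode(space, params))
        y_obs.append(score)
        trace_rows.append({**params, "score": score})
        return score

    if total_points == 1:
        params = {d.name: d.values[0] for d in space}
        score = evaluate(params)
        return BoResult(params, score, pd.DataFrame(trace_rows), space)

    n_init = min(n_init, n_iter)
    for _ in range(n_init):
        evaluate(_sample_params(space, rng))

    kernel = (ConstantKernel(1.0)
              * Matern(length_scale=0.2, length_scale_bounds=(1e-2, 1e1),
                       nu=2.5)
              + WhiteKernel(noise_level=1e-6,
                            noise_level_bounds=(1e-10, 1e-2)))
    # exhaustive acquisition scoring for small spaces, random pool otherwise
    full_grid = None
    if total_points <= 4 * n_candidates:
        from itertools import product
        full_grid = [dict(zip([d.name for d in space], vals))
                     for vals in product(*[d.values for d in space])]
    for _ in range(n_iter - n_init):
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      alpha=1e-10, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.asarray(X_obs), np.asarray(y_obs))
        if full_grid is not None:
            cands = full_grid
        else:
            cands = [_sample_params(space, rng) for _ in range(n_candidates)]
        cands = [c for c in cands
                 if tuple(c[d.name] for d in space) not in evaluated]
        if not cands:
            break
        Xc = np.asarray([_encode(space, c) for c in cands])
        mu, sd = gp.predict(Xc, return_std=True)
        best = max(y_obs)
        xi = 1e-4
        z = np.where(sd > 1e-12, (mu - best - xi) / np.maximum(sd, 1e-12), 0.0)
        ei = (mu - best - xi) * norm.cdf(z) + sd * norm.pdf(z)
        ei[sd <= 1e-12] = 0.0
        evaluate(cands[int(np.argmax(ei))])

    trace = pd.DataFrame(trace_rows)
    trace["incumbent"] = trace["score"].cummax()
    i_best = int(trace["score"].idxmax())
    best_params = {d.name: trace.loc[i_best, d.name] for d in space}
    # restore python types (pandas may promote ints)
    for d in space:
        if not d.categorical:
            best_params[d.name] = int(best_params[d.name])
        elif pd.isna(best_params[d.name]):
            best_params[d.name] = None
    return BoResult(best_params, float(trace.loc[i_best, "score"]), trace, space)


def tune_random_forest(pairs: pd.DataFrame, feature_mask=None, seed: int = 0,
                       n_iter: int = 40) -> BoResult:
    """Tune the random forest on mean 5-fold F1 over the default space."""
    from .models import ModelSpec, cross_validate

    def objective(params: dict) -> float:
        spec = ModelSpec("random_forest", dict(params))
        return cross_validate(pairs, spec, feature_mask=feature_mask,
                              seed=seed).mean_f1

    return bayes_optimize(objective, default_rf_space(), n_iter=n_iter,
                          seed=seed)
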