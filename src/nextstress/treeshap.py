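"""Exact additive (Shapley) attributions for scikit-learn tree ensembles.

Interventional formulation: the value of a coalition S for input x is the
model output averaged over a background sample z with the features in S
taken from x and the rest from z. For a single tree and a single (x, z)
pair this game is a sum over leaves of unanimity games: a leaf is reached
iff every path feature where x and z disagree takes the direction of
whichever of the two is "active", so its Shapley contribution has the
closed form

    phi_i = +v * (|A|-1)! |B|! / (|A|+|B|)!   for i in A
    phi_i = -v * |A|! (|B|-1)! / (|A|+|B|)!   for i in B

where A (resp. B) is the set of path features whose conditions only x
(resp. only z) satisfies, and v the leaf value. Features on which x and z
agree are null players. Attributions are averaged over the background and
summed over trees, so local accuracy

    base_value + sum_i phi_i(x) = f(x)

holds to machine precision (base_value = mean background output).
"""

from __future__ import annotations

from math import lgamma

import numpy as np

__all__ = ["tree_shap_values", "model_output", "sampling_shap_values"]


def _leaf_paths(tree):
    """DFS the sklearn tree_ structure; yield (leaf_id, conditions) where
    conditions is a list of (feature, threshold, go_left)."""
    left, right = tree.children_left, tree.children_right
    feat, thr = tree.feature, tree.threshold
    paths = []
    stack = [(0, [])]
    while stack:
        node, conds = stack.pop()
        if left[node] == -1:
            paths.append((node, conds))
            continue
        stack.append((left[node], conds + [(feat[node], thr[node], True)]))
        stack.append((right[node], conds + [(feat[node], thr[node], False)]))
    return paths


def _leaf_values(estimator):
    """Per-node output values and the additive scale of one tree."""
    tree = estimator.tree_
    v = tree.value  # (n_nodes, 1, n_out)
    if v.shape[2] > 1:  # classifier: probability of class 1
        totals = v[:, 0, :].sum(axis=1, keepdims=True)
        vals = v[:, 0, 1] / np.maximum(totals[:, 0], 1e-300)
    else:
        vals = v[:, 0, 0]
    return vals


def _weight_tables(kmax: int):
    """Wpos[a, b] = (a-1)! b! / (a+b)!, Wneg[a, b] = a! (b-1)! / (a+b)!."""
    a = np.arange(kmax + 1)[:, None].astype(float)
    b = np.arange(kmax + 1)[None, :].astype(float)
    lg = np.vectorize(lgamma)
    with np.errstate(all="ignore"):
        wpos = np.exp(lg(np.maximum(a, 1)) + lg(b + 1) - lg(a + b + 1))
        wneg = np.exp(lg(a + 1) + lg(np.maximum(b, 1)) - lg(a + b + 1))
    wpos[0, :] = 0.0
    wneg[:, 0] = 0.0
    return wpos, wneg


def _component_trees(model):
    """(estimators, per-tree scale) for supported sklearn models."""
    name = type(model).__name__
    if hasattr(model, "tree_"):
        return [model], 1.0
    if name in ("RandomForestClassifier", "RandomForestRegressor"):
        return list(model.estimators_), 1.0 / len(model.estimators_)
    raise ValueError(f"exact tree attribution does not support {name}")


def model_output(model, X: np.ndarray) -> np.ndarray:
    """The output scale being attributed (probability of class 1 for
    classifiers, prediction for regressors)."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.predict(X)


def tree_shap_values(model, X: np.ndarray, background: np.ndarray):
    """Exact interventional Shapley values.

    Returns (phi (n, p), base_value). ``background`` is the reference
    sample (training-fold rows); attribution cost grows linearly in its
    size, so a subsample of a few dozen rows is typical.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(background, dtype=float)
    if X.ndim != 2 or Z.ndim != 2 or X.shape[1] != Z.shape[1]:
        raise ValueError("foreground and background must share feature count")
    n_feat = getattr(model, "n_features_in_", X.shape[1])
    if X.shape[1] != n_feat:
        raise ValueError("feature count does not match the fitted model")
    estimators, scale = _component_trees(model)
    n, m, p = X.shape[0], Z.shape[0], X.shape[1]
    phi = np.zeros((n, p))
    max_depth = max(int(e.tree_.max_depth) for e in estimators)
    wpos, wneg = _weight_tables(max_depth + 1)
    for est in estimators:
        vals = _leaf_values(est)
        for leaf, conds in _leaf_paths(est.tree_):
            v = float(vals[leaf]) * scale
            if not conds:
                continue  # single-leaf tree: constant, no attribution
            feats = {}
            for f, t, go_left in conds:
                feats.setdefault(f, []).append((t, go_left))
            f_ids = list(feats)
            x_ok = np.ones((n, len(f_ids)), dtype=bool)
            z_ok = np.ones((m, len(f_ids)), dtype=bool)
            for i, f in enumerate(f_ids):
                for t, go_left in feats[f]:
                    if go_left:
                        x_ok[:, i] &= X[:, f] <= t
                        z_ok[:, i] &= Z[:, f] <= t
                    else:
                        x_ok[:, i] &= X[:, f] > t
                        z_ok[:, i] &= Z[:, f] > t
            xo = x_ok[:, :, None]           # (n, k, 1)
            zo = z_ok.T[None, :, :]         # (1, k, m)
            reach = np.logical_or(xo, zo).all(axis=1)          # (n, m)
            if not reach.any():
                continue
            a = np.logical_and(xo, ~zo).sum(axis=1)            # (n, m)
            b = np.logical_and(~xo, zo).sum(axis=1)
            wp = wpos[a, b] * reach
            wn = wneg[a, b] * reach
            for i, f in enumerate(f_ids):
                in_a = x_ok[:, i][:, None] & ~z_ok[:, i][None, :]
                in_b = ~x_ok[:, i][:, None] & z_ok[:, i][None, :]
                phi[:, f] += v * (wp * in_a).sum(axis=1) / m
                phi[:, f] -= v * (wn * in_b).sum(axis=1) / m
    base = float(np.mean(model_output(model, Z)))
    return phi, base


def sampling_shap_values(predict_fn, X: np.ndarray, background: np.ndarray,
                         n_permutations: int = 200, seed: int = 0):
    """Permutation-sampling Shapley fallback for non-tree models.

    Monte-Carlo marginal contributions over random feature orderings;
    unbiased, with sampling error shrinking as 1/sqrt(n_permutations).
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(background, dtype=float)
    n, p = X.shape
    phi = np.zeros((n, p))
    base = float(np.mean(predict_fn(Z)))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        z = Z[rng.integers(Z.shape[0], size=n)]
        cur = z.copy()
        prev = predict_fn(cur)
        for f in order:
            cur[:, f] = X[:, f]
            nxt = predict_fn(cur)
            phi[:, f] += nxt - prev
            prev = nxt
    return phi / n_permutations, base
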