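"""Day-level feature engineering: the 69-column modeling table.

Feature groups (counts fixed and column order frozen):
  30 HRV day means  +  17 duration  +  13 EMA  +  4 intervention  +  5 covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hrv import HRV_FEATURES
from .synthetic import EMA_QUESTIONS, PSS_QUESTIONS, PSS_REVERSED

DURATION_THRESHOLDS = (1, 2, 5, 10)
DURATION_FEATURES = [
    f"{stat}_w{w}"
    for w in DURATION_THRESHOLDS
    for stat in ("consec_stress_min", "stress_episodes",
                 "stress_min_pct_wear", "episode_pct")
] + ["binary_stress"]
EMA_FEATURES = [f"ema_{q}" for q in EMA_QUESTIONS] + ["ema_pss4_daily"]
INTERVENTION_FEATURES = [
    "intervention_day", "count_intervention",
    "jit_intervention_day", "count_jit_intervention",
]
COVARIATE_FEATURES = [
    "age", "gestational_age_enroll", "n_prior_pregnancies",
    "n_prior_children", "epds_score",
]
HRV_DAY_FEATURES = [f"hrv_{f}" for f in HRV_FEATURES]
FEATURE_COLUMNS = (HRV_DAY_FEATURES + DURATION_FEATURES + EMA_FEATURES
                   + INTERVENTION_FEATURES + COVARIATE_FEATURES)
assert len(FEATURE_COLUMNS) == 69

FEATURE_GROUPS = {
    "sensor": HRV_DAY_FEATURES + DURATION_FEATURES,
    "ema": EMA_FEATURES,
    "intervention": INTERVENTION_FEATURES,
    "covariates": COVARIATE_FEATURES,
}


def fit_minute_stress_model(minute_vectors, state_labels, seed: int = 0):
    """Margin-based minute stress classifier (grid-searched SVM).

    Fitted on standardized 30-feature minute vectors against the
    generator's minute states (the retrainable stand-in for a pretrained
    minute-level stress model). Returns a fitted sklearn estimator whose
    ``predict`` yields 1 = stress positive.
    """
    from sklearn.impute import SimpleImputer
    from sklearn.model_selection import GridSearchCV
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = np.asarray(minute_vectors, dtype=float)
    y = np.asarray(state_labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("minute stress training needs both classes")
    pipe = Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
        ("svm", SVC()),
    ])
    grid = {"svm__C": [0.1, 1.0, 10.0], "svm__kernel": ["linear", "rbf"]}
    from sklearn.model_selection import StratifiedKFold
    cv = StratifiedKFold(3, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=cv, n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_


def stress_runs(minute_calls: np.ndarray) -> np.ndarray:
    """Lengths of maximal consecutive stress-positive runs.

    ``minute_calls`` is an int/bool/NaN sequence over wear minutes in
    chronological order; NaN (invalid/non-wear) minutes break runs.
    """
    calls = np.asarray(minute_calls, dtype=float)
    pos = np.nan_to_num(calls, nan=0.0) > 0.5
    padded = np.concatenate(([False], pos, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return edges[1::2] - edges[::2]


def duration_features(minute_calls, wear_minutes: int) -> pd.Series:
    """17 duration features from minute-level stress calls.

    For each minimum-run threshold W in {1, 2, 5, 10}: total minutes in
    stress runs of length >= W, the count of such runs (episodes), those
    minutes as % of wear time, and those episodes as % of all stress
    episodes; plus the day's binary stress indicator (stress minutes
    > 50% of wear).
    """
    out = {}
    if wear_minutes <= 0:
        return pd.Series({f: 0.0 for f in DURATION_FEATURES})
    runs = stress_runs(minute_calls)
    total_eps = runs.size
    for w in DURATION_THRESHOLDS:
        keep = runs[runs >= w]
        minutes = float(keep.sum())
        eps = float(keep.size)
        out[f"consec_stress_min_w{w}"] = minutes
        out[f"stress_episodes_w{w}"] = eps
        out[f"stress_min_pct_wear_w{w}"] = 100.0 * minutes / wear_minutes
        out[f"episode_pct_w{w}"] = 100.0 * eps / total_eps if total_eps else 0.0
    out["binary_stress"] = float(out["consec_stress_min_w1"] / wear_minutes > 0.5)
    return pd.Series(out).reindex(DURATION_FEATURES)


def pss4_score(responses: dict) -> float:
    """Cohen PSS-4: positively worded items reverse-scored, summed (0-16)."""
    total = 0.0
    for q in PSS_QUESTIONS:
        r = responses[q]
        total += (4 - r) if q in PSS_REVERSED else r
    return total


def ema_day_features(ema_log: pd.DataFrame, participant_id: str,
                     day: str) -> pd.Series:
    """13 EMA features for one participant-day.

    Twelve per-question daily means of the raw responses, plus the daily
    mean of the per-prompt PSS-4 score. Days without any answered prompt
    come back all-NaN.
    """
    sel = ema_log[(ema_log["participant_id"] == participant_id)
                  & (ema_log["date"] == day)]
    out = pd.Series(np.nan, index=EMA_FEATURES)
    if sel.empty:
        return out
    means = sel.groupby("question_id")["response"].mean()
    for q in EMA_QUESTIONS:
        if q in means.index:
            out[f"ema_{q}"] = float(means[q])
    pss_scores = []
    for _, prompt in sel.groupby("prompt_index"):
        resp = dict(zip(prompt["question_id"], prompt["response"]))
        if all(q in resp for q in PSS_QUESTIONS):
            pss_scores.append(pss4_score(resp))
    if pss_scores:
        out["ema_pss4_daily"] = float(np.mean(pss_scores))
    return out


def intervention_features(log: pd.DataFrame, participant_id: str,
                          target_day: str) -> pd.Series:
    """4 intervention features referenced to the day before ``target_day``.

    intervention_day / jit_intervention_day flag whether the prior day had
    a 1:1 session / JIT message; the counts are cumulative through the
    prior day.
    """
    target = pd.Timestamp(target_day)
    prior = target - pd.Timedelta(days=1)
    sel = log[log["participant_id"] == participant_id] if len(log) else log
    if len(sel) == 0:
        return pd.Series(0.0, index=INTERVENTION_FEATURES)
    dates = pd.to_datetime(sel["date"])
    upto = sel[dates <= prior]
    on_prior = sel[dates == prior]
    return pd.Series({
        "intervention_day": float((on_prior["kind"] == "one_on_one").any()),
        "count_intervention": float((upto["kind"] == "one_on_one").sum()),
        "jit_intervention_day": float((on_prior["kind"] == "jit").any()),
        "count_jit_intervention": float((upto["kind"] == "jit").sum()),
    }).reindex(INTERVENTION_FEATURES)


def assemble_day_rows(hrv_day: pd.DataFrame, duration: pd.DataFrame,
                      ema: pd.DataFrame, intervention: pd.DataFrame,
                      profiles: list) -> pd.DataFrame:
    """Join the feature blocks into the 69-column day table.

    Each block is indexed by (participant_id, date). Days missing a block
    keep NaN for that block's columns (imputation happens inside training
    folds, never here). Covariates are always present.
    """
    key = ["participant_id", "date"]
    blocks = [b.set_index(key) for b in (hrv_day, duration, ema, intervention)
              if len(b)]
    if not blocks:
        raise ValueError("no feature blocks supplied")
    for b in blocks:
        if b.index.duplicated().any():
            raise ValueError("duplicate participant-day keys in a block")
    table = pd.concat(blocks, axis=1)
    cov = pd.DataFrame([
        {"participant_id": p.participant_id,
         "age": p.age,
         "gestational_age_enroll": p.gestational_age_enroll,
         "n_prior_pregnancies": p.n_prior_pregnancies,
         "n_prior_children": p.n_prior_children,
         "epds_score": p.epds_score}
        for p in profiles
    ]).set_index("participant_id")
    table = table.reset_index()
    table = table.merge(cov, left_on="participant_id", right_index=True,
                        how="left")
    for col in FEATURE_COLUMNS:
        if col not in table.columns:
            table[col] = np.nan
    id_cols = key + (["wear_minutes"] if "wear_minutes" in table.columns else [])
    return table[id_cols + FEATURE_COLUMNS]
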