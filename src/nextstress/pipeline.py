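"""End-to-end orchestration: cohort bundle -> day table -> pairs -> models.

Two tiers share one implementation:

* the *signal tier* (waveform ECG -> noise screen -> R peaks -> IBIs) is
  exercised by the benchmark helpers at the bottom of this module;
* the *study tier* consumes per-minute IBI series (either the output of
  the signal tier or the generator's ground-truth beat series), builds
  the 69-feature day table, labels days, and forms next-day pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ecg as ecgmod
from .features import (EMA_FEATURES, FEATURE_COLUMNS, assemble_day_rows,
                       duration_features, fit_minute_stress_model,
                       pss4_score)
from .hrv import HRV_FEATURES, hrv_matrix
from .labels import (build_nextday_pairs, perceived_day_label,
                     physiological_day_label)
from .synthetic import (CohortBundle, EMA_QUESTIONS, PSS_QUESTIONS,
                        generate_cohort)


@dataclass
class StudyData:
    bundle: CohortBundle
    day_rows: pd.DataFrame          # 69-feature table keyed by pid/date
    labels: pd.DataFrame            # pid, date, phys_label, perc_label, ...
    pairs_phys: pd.DataFrame
    pairs_perc: pd.DataFrame
    minute_accuracy: float          # held-out accuracy of the minute model
    minute_model: object = None


def minute_ibis_from_beats(beat_times_ms: np.ndarray, amplitudes: np.ndarray,
                           n_minutes: int):
    """Split a day's beat series into per-minute IBI and amplitude lists.

    An IBI belongs to the minute containing its onset beat; its amplitude
    entry is the onset beat's amplitude.
    """
    t = np.asarray(beat_times_ms, dtype=float)
    if t.size < 2:
        return ([np.empty(0)] * n_minutes, [np.empty(0)] * n_minutes)
    onsets = t[:-1]
    ibis = np.diff(t)
    amps = np.asarray(amplitudes, dtype=float)[:-1]
    edges = np.searchsorted(onsets, np.arange(1, n_minutes) * 60_000.0)
    ibi_list = np.split(ibis, edges)
    amp_list = np.split(amps, edges)
    return list(ibi_list), list(amp_list)


def minute_ibis_from_table(ibis: pd.DataFrame, peaks: pd.DataFrame,
                           n_minutes: int):
    """Same split, but from the signal-tier output tables."""
    onsets = ibis["onset_ms"].to_numpy()
    vals = ibis["ibi_ms"].to_numpy()
    amp_by_time = dict(zip(peaks["time_ms"], peaks["amplitude"]))
    amps = np.array([amp_by_time.get(t, 1.0) for t in onsets])
    minute = np.minimum((onsets // 60_000).astype(int), n_minutes - 1)
    ibi_list = [vals[minute == m] for m in range(n_minutes)]
    amp_list = [amps[minute == m] for m in range(n_minutes)]
    return ibi_list, amp_list


def _bulk_ema_features(ema: pd.DataFrame) -> pd.DataFrame:
    """13 EMA features for every participant-day at once."""
    rows = []
    if ema.empty:
        return pd.DataFrame(columns=["participant_id", "date"] + EMA_FEATURES)
    for (pid, day), sel in ema.groupby(["participant_id", "date"]):
        rec = {"participant_id": pid, "date": day}
        means = sel.groupby("question_id")["response"].mean()
        for q in EMA_QUESTIONS:
            rec[f"ema_{q}"] = float(means[q]) if q in means.index else np.nan
        scores = []
        for _, prompt in sel.groupby("prompt_index"):
            resp = dict(zip(prompt["question_id"], prompt["response"]))
            if all(q in resp for q in PSS_QUESTIONS):
                scores.append(pss4_score(resp))
        rec["ema_pss4_daily"] = float(np.mean(scores)) if scores else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def _bulk_intervention_features(interventions: pd.DataFrame,
                                keys: pd.DataFrame) -> pd.DataFrame:
    """Intervention features for every (pid, date) key; the prior day
    relative to the prediction target is the key day itself."""
    out = []
    iv = interventions.copy()
    if len(iv):
        iv["date"] = pd.to_datetime(iv["date"])
    for pid, grp in keys.groupby("participant_id"):
        sel = iv[iv["participant_id"] == pid] if len(iv) else iv
        for day in grp["date"]:
            d = pd.Timestamp(day)
            if len(sel):
                upto = sel[sel["date"] <= d]
                on_day = sel[sel["date"] == d]
                rec = {
                    "intervention_day": float((on_day["kind"] == "one_on_one").any()),
                    "count_intervention": float((upto["kind"] == "one_on_one").sum()),
                    "jit_intervention_day": float((on_day["kind"] == "jit").any()),
                    "count_jit_intervention": float((upto["kind"] == "jit").sum()),
                }
            else:
                rec = dict.fromkeys(
                    ["intervention_day", "count_intervention",
                     "jit_intervention_day", "count_jit_intervention"], 0.0)
            rec.update({"participant_id": pid, "date": day})
            out.append(rec)
    return pd.DataFrame(out)


def build_study(bundle: CohortBundle, seed: int = 0,
                n_train_minutes: int = 12000,
                minute_lists: dict | None = None) -> StudyData:
    """Run the study tier on a cohort bundle.

    ``minute_lists`` optionally maps (pid, date) -> (ibi_list, amp_list)
    produced by the signal tier; by default the generator's ground-truth
    beat series are used (the signal tier is validated separately against
    the same ground truth).
    """
    rng = np.random.default_rng(seed)
    wear = int(bundle.days["wear_minutes"].iloc[0])
    keys, all_ibis, all_amps, all_states = [], [], [], []
    for _, row in bundle.days.iterrows():
        key = (row["participant_id"], row["date"])
        if minute_lists is not None and key in minute_lists:
            ibi_list, amp_list = minute_lists[key]
        else:
            b = bundle.beats[key]
            ibi_list, amp_list = minute_ibis_from_beats(
                b.beat_times_ms, b.beat_amplitudes, wear)
        keys.append(key)
        all_ibis.extend(ibi_list)
        all_amps.extend(amp_list)
        all_states.append(bundle.tracks[key].minute_states)
    states = np.concatenate(all_states)
    hrv = hrv_matrix(all_ibis, all_amps)
    valid = hrv["mean_ibi"].notna().to_numpy()

    # minute stress model: train on a labelled subsample, apply everywhere
    vidx = np.flatnonzero(valid)
    n_train = min(n_train_minutes, vidx.size // 2)
    train = rng.choice(vidx, size=n_train, replace=False)
    test_pool = np.setdiff1d(vidx, train)
    ho = rng.choice(test_pool, size=min(4000, test_pool.size), replace=False)
    Xv = hrv.to_numpy(dtype=float)
    model = fit_minute_stress_model(Xv[train], states[train], seed=seed)
    acc = float(np.mean(model.predict(Xv[ho]) == states[ho].astype(int)))
    calls = np.full(len(hrv), np.nan)
    for lo in range(0, vidx.size, 50_000):
        chunk = vidx[lo:lo + 50_000]
        calls[chunk] = model.predict(Xv[chunk])

    # per-day blocks
    hrv_day_rows, dur_rows, label_rows = [], [], []
    for i, key in enumerate(keys):
        pid, day = key
        sl = slice(i * wear, (i + 1) * wear)
        day_hrv = hrv.iloc[sl]
        day_valid = valid[sl]
        rec = {"participant_id": pid, "date": day,
               "wear_minutes": int(day_valid.sum())}
        means = day_hrv[day_valid].mean(axis=0) if day_valid.any() else \
            pd.Series(np.nan, index=HRV_FEATURES)
        for f in HRV_FEATURES:
            rec[f"hrv_{f}"] = means[f]
        hrv_day_rows.append(rec)
        day_calls = calls[sl]
        wear_eff = int(day_valid.sum())
        dur = duration_features(day_calls, wear_eff)
        dur_rows.append({"participant_id": pid, "date": day, **dur.to_dict()})
        phys, frac = physiological_day_label(day_calls, wear_eff)
        label_rows.append({"participant_id": pid, "date": day,
                           "phys_label": phys, "stress_fraction": frac})

    hrv_day = pd.DataFrame(hrv_day_rows)
    duration = pd.DataFrame(dur_rows)
    ema_feat = _bulk_ema_features(bundle.ema)
    key_df = bundle.days[["participant_id", "date"]]
    iv_feat = _bulk_intervention_features(bundle.interventions, key_df)
    day_rows = assemble_day_rows(
        hrv_day, duration,
        ema_feat if len(ema_feat) else key_df.copy(),
        iv_feat, bundle.profiles)

    labels = pd.DataFrame(label_rows)
    pss = ema_feat.set_index(["participant_id", "date"])["ema_pss4_daily"] \
        if len(ema_feat) else pd.Series(dtype=float)
    labels["perc_label"] = [
        perceived_day_label(pss.get((r["participant_id"], r["date"]), np.nan))
        for _, r in labels.iterrows()
    ]
    labels["phys_label"] = labels["phys_label"].astype("float")
    labels["perc_label"] = labels["perc_label"].astype("float")

    pairs_phys = build_nextday_pairs(day_rows, labels, "phys")
    pairs_perc = build_nextday_pairs(day_rows, labels, "perc")
    return StudyData(bundle, day_rows, labels, pairs_phys, pairs_perc,
                     acc, model)


def run_study(n_participants: int, n_days: int, seed: int,
              config=None, n_train_minutes: int = 12000) -> StudyData:
    bundle = generate_cohort(n_participants, n_days, seed, config)
    return build_study(bundle, seed=seed, n_train_minutes=n_train_minutes)


def benchmark_baselines(pairs: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """5-fold CV of all six baseline specs on one pair table."""
    from .models import BASELINE_SPECS, cross_validate

    rows = []
    for name, spec in BASELINE_SPECS.items():
        res = cross_validate(pairs, spec, seed=seed)
        rows.append({"model": name,
                     "mean_precision": res.mean_precision,
                     "mean_recall": res.mean_recall,
                     "mean_f1": res.mean_f1,
                     "sd_f1": float(np.std(res.fold_f1))})
    return pd.DataFrame(rows).sort_values("mean_f1", ascending=False) \
        .reset_index(drop=True)


def select_and_tune(pairs: pd.DataFrame, seed: int = 0,
                    n_iter: int = 35):
    """Global CFS, then GP tuning of the random forest on the selection.

    Returns (selected feature names, BoResult, tuned CvResult). Selection
    is run once on all pairs, mirroring a selection-then-tune protocol;
    the per-fold alternative is available through
    ``cfs.cfs_column_selector`` with ``cross_validate(select=...)``.
    """
    from .bayesopt import tune_random_forest
    from .cfs import cfs_select
    from .models import ModelSpec, cross_validate

    X = pairs[FEATURE_COLUMNS].to_numpy(dtype=float)
    med = np.nanmedian(X, axis=0)
    X_imp = np.where(np.isfinite(X), X, med[None, :])
    y = pairs["target"].to_numpy(dtype=int)
    res = cfs_select(X_imp, y)
    selected = [FEATURE_COLUMNS[j] for j in res.selected] or FEATURE_COLUMNS
    bo = tune_random_forest(pairs, feature_mask=selected, seed=seed,
                            n_iter=n_iter)
    spec = ModelSpec("random_forest", dict(bo.best_params))
    tuned = cross_validate(pairs, spec, feature_mask=selected, seed=seed)
    return selected, bo, tuned


def explain_out_of_fold(pairs: pd.DataFrame, feature_cols: list,
                        params: dict, seed: int = 0,
                        background_size: int = 40):
    """Out-of-fold exact tree attributions for the tuned forest.

    Per fold: impute with training medians, fit the forest on the
    training rows, attribute the test rows against a training-fold
    background subsample. Returns an AttributionMatrix over all rows.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import KFold

    from .explain import AttributionMatrix, attribute

    X = pairs[feature_cols].to_numpy(dtype=float)
    y = pairs["target"].to_numpy(dtype=int)
    rng = np.random.default_rng(seed)
    phi_all = np.zeros_like(X)
    xin_all = np.zeros_like(X)
    bases = []
    for tr, te in KFold(5, shuffle=True, random_state=seed).split(X):
        med = np.nanmedian(X[tr], axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        X_tr = np.where(np.isfinite(X[tr]), X[tr], med[None, :])
        X_te = np.where(np.isfinite(X[te]), X[te], med[None, :])
        rf = RandomForestClassifier(random_state=seed, **params)
        rf.fit(X_tr, y[tr])
        bg = X_tr[rng.choice(len(X_tr), size=min(background_size, len(X_tr)),
                             replace=False)]
        attr = attribute(rf, pd.DataFrame(X_te, columns=feature_cols),
                         pd.DataFrame(bg, columns=feature_cols))
        phi_all[te] = attr.values.to_numpy()
        xin_all[te] = X_te
        bases.append(attr.base_value)
    return AttributionMatrix(pd.DataFrame(phi_all, columns=feature_cols),
                             float(np.mean(bases)),
                             pd.DataFrame(xin_all, columns=feature_cols))


# ---------------------------------------------------------------------------
# signal-tier benchmarks (waveform ECG against generator ground truth)
# ---------------------------------------------------------------------------

def _render_minutes(n_minutes, seed, bpm_range=(50, 110),
                    noise_fraction=0.0, dropout=0.0):
    """Render independent one-minute waveforms at mixed rates."""
    from .synthetic import EcgGenConfig, StateTrack, render_ecg

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_minutes):
        bpm = rng.uniform(*bpm_range)
        cfg = EcgGenConfig(calm_ibi_mean=60000.0 / bpm,
                           calm_ibi_sd=0.05 * 60000.0 / bpm,
                           noise_segment_fraction=noise_fraction,
                           dropout_fraction=dropout)
        track = StateTrack("", np.zeros(1, dtype=bool), 0.0, 1.0)
        out.append((render_ecg(track, cfg, rng), cfg))
    return out


def match_peaks(detected_ms, truth_ms, tol_ms=50.0):
    """Greedy nearest matching; returns (tp, fp, fn, abs errors of matches)."""
    detected = np.sort(np.asarray(detected_ms, dtype=float))
    truth = np.sort(np.asarray(truth_ms, dtype=float))
    used = np.zeros(truth.size, dtype=bool)
    errors = []
    tp = 0
    for d in detected:
        j = np.searchsorted(truth, d)
        best, best_err = -1, tol_ms
        for k in (j - 1, j):
            if 0 <= k < truth.size and not used[k]:
                err = abs(truth[k] - d)
                if err <= best_err:
                    best, best_err = k, err
        if best >= 0:
            used[best] = True
            tp += 1
            errors.append(best_err)
    fp = detected.size - tp
    fn = truth.size - tp
    return tp, fp, fn, np.asarray(errors)


def rpeak_benchmark(n_minutes: int, seed: int,
                    bpm_range=(50, 110)) -> dict:
    """Detection F1 and timing error on clean synthetic minutes."""
    tp = fp = fn = 0
    errs = []
    for day, cfg in _render_minutes(n_minutes, seed, bpm_range):
        times, _, _ = ecgmod.detect_r_peaks(day.voltage, cfg.sampling_rate,
                                            t0_ms=day.t_ms[0])
        t, f, n, e = match_peaks(times, day.beat_times_ms)
        tp += t; fp += f; fn += n
        errs.append(e)
    errs = np.concatenate(errs) if errs else np.zeros(0)
    from .models import metrics
    precision, recall, f1 = metrics(tp, fp, fn, 0)
    return {"f1": f1, "precision": precision, "recall": recall,
            "mean_abs_error_ms": float(errs.mean()) if errs.size else np.nan,
            "n_true_beats": tp + fn}


def noise_training_set(seed: int, n_minutes: int = 40):
    """Labelled 0.6-s intervals from half-noisy rendered minutes."""
    from .synthetic import EcgGenConfig, StateTrack, render_ecg

    rng = np.random.default_rng(seed)
    cfg = EcgGenConfig(noise_segment_fraction=0.5, dropout_fraction=0.0)
    track = StateTrack("", np.zeros(n_minutes, dtype=bool), 0.0, 1.0)
    day = render_ecg(track, cfg, rng)
    rate = cfg.sampling_rate
    spm = int(60 * rate)
    feats, labels = [], []
    n_iv = int(round(0.6 * rate))
    for m in range(n_minutes):
        v = day.voltage[m * spm:(m + 1) * spm]
        for lo in range(0, spm - n_iv + 1, n_iv):
            feats.append(ecgmod.interval_noise_features(v[lo:lo + n_iv], rate))
            labels.append(int(day.noise_minutes[m]))
    return np.asarray(feats), np.asarray(labels)


def ibi_pipeline_benchmark(n_days: int, minutes_per_day: int, seed: int,
                           noise_fraction: float = 0.1) -> dict:
    """End-to-end signal tier vs generator truth.

    Renders multi-minute recordings with noisy segments, trains the noise
    ensemble on separately rendered labelled intervals, runs the full
    pipeline, and reports the median absolute IBI error on retained data
    plus the clean-window percentage.
    """
    from .synthetic import EcgGenConfig, StateTrack, render_ecg

    Xn, yn = noise_training_set(seed + 1)
    ens = ecgmod.fit_noise_ensemble(Xn, yn, seed=seed)
    rng = np.random.default_rng(seed)
    errors = []
    clean_pcts = []
    for d in range(n_days):
        cfg = EcgGenConfig(noise_segment_fraction=noise_fraction,
                           dropout_fraction=0.0)
        track = StateTrack("", np.zeros(minutes_per_day, dtype=bool), 0.0, 1.0)
        day = render_ecg(track, cfg, rng)
        rec = ecgmod.EcgRecording(f"bench_{d}", day.t_ms, day.voltage,
                                  cfg.sampling_rate)
        ibis, peaks, report = ecgmod.process_recording(rec, ens)
        clean_pcts.append(report.clean_pct)
        truth_on = day.beat_times_ms[:-1]
        truth_ibi = np.diff(day.beat_times_ms)
        noisy_min = set(np.flatnonzero(day.noise_minutes))
        for onset, ibi in zip(ibis["onset_ms"], ibis["ibi_ms"]):
            m = int(onset // 60000)
            if m in noisy_min or int((onset + ibi) // 60000) in noisy_min:
                continue
            j = np.searchsorted(truth_on, onset)
            cand = [k for k in (j - 1, j) if 0 <= k < truth_on.size]
            if not cand:
                continue
            k = min(cand, key=lambda k: abs(truth_on[k] - onset))
            if abs(truth_on[k] - onset) <= 100.0:
                errors.append(abs(ibi - truth_ibi[k]))
    errors = np.asarray(errors)
    return {
        "median_abs_error_ms": float(np.median(errors)) if errors.size else np.nan,
        "n_ibis_scored": int(errors.size),
        "mean_clean_pct": float(np.mean(clean_pcts)),
    }
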