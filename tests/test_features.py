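"""Feature engineering: duration runs, EMA scoring, interventions, assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nextstress as ns
from nextstress.features import (DURATION_FEATURES, DURATION_THRESHOLDS,
                                 EMA_FEATURES, FEATURE_COLUMNS,
                                 INTERVENTION_FEATURES, assemble_day_rows,
                                 duration_features, ema_day_features,
                                 fit_minute_stress_model,
                                 intervention_features, pss4_score)
from nextstress.synthetic import EMA_QUESTIONS


def brute_force_duration(calls, wear):
    """Independent run-length scanner (oracle)."""
    runs = [len(list(g)) for k, g in itertools.groupby(
        [bool(c) and not (isinstance(c, float) and np.isnan(c)) for c in calls])
        if k]
    out = {}
    total = len(runs)
    for w in DURATION_THRESHOLDS:
        mins = sum(r for r in runs if r >= w)
        eps = sum(1 for r in runs if r >= w)
        out[f"consec_stress_min_w{w}"] = float(mins)
        out[f"stress_episodes_w{w}"] = float(eps)
        out[f"stress_min_pct_wear_w{w}"] = 100.0 * mins / wear if wear else 0.0
        out[f"episode_pct_w{w}"] = 100.0 * eps / total if total else 0.0
    out["binary_stress"] = float(wear > 0 and
                                 out["consec_stress_min_w1"] / wear > 0.5)
    return out


class TestDuration:
    def test_worked_example(self):
        calls = ([1] * 12 + [0] * 5 + [1] * 3 + [0] * 4 + [1] * 7
                 + [0] * (480 - 31))
        d = duration_features(np.array(calls, dtype=float), 480)
        assert d["consec_stress_min_w10"] == 12 and d["stress_episodes_w10"] == 1
        assert d["consec_stress_min_w5"] == 19 and d["stress_episodes_w5"] == 2
        assert d["consec_stress_min_w1"] == 22 and d["stress_episodes_w1"] == 3
        assert d["stress_min_pct_wear_w10"] == pytest.approx(2.5)

    def test_all_negative_day(self):
        d = duration_features(np.zeros(480), 480)
        assert (d == 0).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(5, 300))
            calls = (rng.random(n) < rng.uniform(0.1, 0.9)).astype(float)
            if rng.random() < 0.5:  # sprinkle invalid minutes: they break runs
                calls[rng.random(n) < 0.1] = np.nan
            got = duration_features(calls, n)
            want = brute_force_duration(calls.tolist(), n)
            for k, v in want.items():
                assert got[k] == pytest.approx(v), k

    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=60)
    def test_monotone_in_threshold(self, calls):
        d = duration_features(np.array(calls, dtype=float), len(calls))
        for a, b in zip(DURATION_THRESHOLDS, DURATION_THRESHOLDS[1:]):
            assert d[f"consec_stress_min_w{a}"] >= d[f"consec_stress_min_w{b}"]
            assert d[f"stress_episodes_w{a}"] >= d[f"stress_episodes_w{b}"]

    def test_zero_wear_flagged_all_zero(self):
        d = duration_features(np.array([]), 0)
        assert (d == 0).all()


def _ema_frame(rows):
    return pd.DataFrame(rows, columns=["participant_id", "date",
                                       "prompt_index", "question_id",
                                       "response"])


class TestEmaFeatures:
    def test_pss4_worked_example(self):
        # control=3, overcome=3, confident stored raw 1 (scored 3),
        # your-way stored raw 1 (scored 3) -> total 12
        resp = {"pss_control": 3, "pss_overcome": 3,
                "pss_confident": 1, "pss_your_way": 1}
        assert pss4_score(resp) == 12

    def test_pss4_range_bounds(self):
        low = {"pss_control": 0, "pss_overcome": 0,
               "pss_confident": 4, "pss_your_way": 4}
        high = {"pss_control": 4, "pss_overcome": 4,
                "pss_confident": 0, "pss_your_way": 0}
        assert pss4_score(low) == 0
        assert pss4_score(high) == 16

    def test_day_features_count_and_means(self):
        rows = [("P1", "2021-03-01", 0, q, 2) for q in EMA_QUESTIONS]
        rows += [("P1", "2021-03-01", 1, q, 4) for q in EMA_QUESTIONS]
        out = ema_day_features(_ema_frame(rows), "P1", "2021-03-01")
        assert len(out) == 13
        assert out["ema_happy"] == 3.0
        # prompt PSS-4: (2+2+2+2)=8 and (4+4+0+0)=8 -> daily mean 8
        assert out["ema_pss4_daily"] == 8.0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(4)
        rows = [("P1", "2021-03-01", p, q, int(rng.integers(0, 5)))
                for p in range(3) for q in EMA_QUESTIONS]
        a = ema_day_features(_ema_frame(rows), "P1", "2021-03-01")
        b = ema_day_features(_ema_frame(rows[::-1]), "P1", "2021-03-01")
        pd.testing.assert_series_equal(a, b)

    def test_no_answers_all_missing(self):
        out = ema_day_features(_ema_frame([]), "P1", "2021-03-01")
        assert out.isna().all() and len(out) == 13


class TestInterventionFeatures:
    def _log(self, days):
        return pd.DataFrame([{"participant_id": "P1",
                              "date": f"2021-03-{d:02d}",
                              "kind": k, "time": "10:00"}
                             for d, k in days])

    def test_worked_example(self):
        log = self._log([(1, "one_on_one"), (8, "one_on_one")])
        out = intervention_features(log, "P1", "2021-03-09")
        assert out["intervention_day"] == 1
        assert out["count_intervention"] == 2

    def test_empty_log(self):
        out = intervention_features(pd.DataFrame(), "P1", "2021-03-09")
        assert (out == 0).all() and len(out) == 4

    def test_counts_non_decreasing(self):
        log = self._log([(1, "one_on_one"), (3, "jit"), (8, "one_on_one"),
                         (10, "jit")])
        counts = [intervention_features(log, "P1", f"2021-03-{d:02d}")
                  ["count_jit_intervention"] for d in range(2, 15)]
        assert counts == sorted(counts)


class TestAssembly:
    def _blocks(self, profiles):
        key = [{"participant_id": "P01", "date": "2021-03-01"}]
        hrv = pd.DataFrame([{**key[0], **{f"hrv_{f}": 1.0
                                          for f in ns.hrv.HRV_FEATURES},
                             "wear_minutes": 480}])
        dur = pd.DataFrame([{**key[0], **{f: 0.0 for f in DURATION_FEATURES}}])
        ema = pd.DataFrame([{**key[0], **{f: 1.0 for f in EMA_FEATURES}}])
        iv = pd.DataFrame([{**key[0], **{f: 0.0 for f in INTERVENTION_FEATURES}}])
        return hrv, dur, ema, iv

    def test_exactly_69_columns_with_decomposition(self, tiny_cohort):
        p = tiny_cohort.profiles
        hrv, dur, ema, iv = self._blocks(p)
        table = assemble_day_rows(hrv, dur, ema, iv, p)
        feature_cols = [c for c in table.columns if c in FEATURE_COLUMNS]
        assert len(feature_cols) == 69
        assert len(FEATURE_COLUMNS) == 30 + 17 + 13 + 4 + 5

    def test_missing_sensor_day_keeps_covariates(self, tiny_cohort):
        p = tiny_cohort.profiles
        _, dur, ema, iv = self._blocks(p)
        table = assemble_day_rows(
            pd.DataFrame(columns=["participant_id", "date"]),
            dur, ema, iv, p)
        row = table.iloc[0]
        assert np.isnan(row["hrv_mean_ibi"])
        assert row["age"] == p[0].age

    def test_duplicate_keys_rejected(self, tiny_cohort):
        p = tiny_cohort.profiles
        hrv, dur, ema, iv = self._blocks(p)
        with pytest.raises(ValueError):
            assemble_day_rows(pd.concat([hrv, hrv]), dur, ema, iv, p)


@pytest.fixture(scope="module")
def vectors():
    from nextstress.hrv import hrv_matrix
    rng = np.random.default_rng(6)
    calm = [rng.normal(850, 60, 70) for _ in range(400)]
    stressed = [rng.normal(700, 36, 85) for _ in range(400)]  # SDNN -40%
    X = hrv_matrix(calm + stressed).to_numpy()
    y = np.r_[np.zeros(400), np.ones(400)].astype(int)
    order = np.random.default_rng(60).permutation(800)
    return X[order], y[order]


class TestMinuteStressModel:
    def test_separability_benchmark(self, vectors):
        X, y = vectors
        rng = np.random.default_rng(7)
        idx = rng.permutation(len(y))
        tr, te = idx[:500], idx[500:]
        model = fit_minute_stress_model(X[tr], y[tr], seed=0)
        assert np.mean(model.predict(X[te]) == y[te]) >= 0.85

    def test_shuffled_labels_at_chance(self, vectors):
        X, y = vectors
        rng = np.random.default_rng(8)
        ys = rng.permutation(y)
        model = fit_minute_stress_model(X[:500], ys[:500], seed=0)
        acc = np.mean(model.predict(X[500:]) == ys[500:])
        se = np.sqrt(0.25 / 300)
        assert abs(acc - 0.5) <= 3 * se + 0.05

    def test_duplicate_evaluation_identical(self, vectors):
        X, y = vectors
        model = fit_minute_stress_model(X[:400], y[:400], seed=0)
        np.testing.assert_array_equal(model.predict(X[400:]),
                                      model.predict(X[400:]))

    def test_single_class_rejected(self, vectors):
        X, y = vectors
        with pytest.raises(ValueError):
            fit_minute_stress_model(X[:100], np.zeros(100), seed=0)
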