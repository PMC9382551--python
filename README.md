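# nextstress

Predicting **next-day stress** from the prior day's wearable ECG,
ecological momentary assessments (EMA), and behavioural-intervention
logs — the setting is a perinatal cohort wearing a single-lead chest
patch during waking hours for about twelve weeks while receiving a
cognitive-behavioural stress-reduction course. The package is for
digital-health and biostatistics researchers who want a fully testable
re-implementation of this kind of pipeline: because the original raw
data are not deposited, a synthetic study generator with exact ground
truth (beat times, noise masks, minute-level stress states, latent
perceived-stress levels) stands in for them, and every stage is
validated against that truth.

Two distinct targets are predicted for day *t+1* from day *t*:

* **physiological stress** — a day is positive when more than 50% of
  wear minutes are classified stress positive by a minute-level HRV
  classifier (reduced heart-rate variability indexes sympathetic
  activation);
* **perceived stress** — a day is positive when the daily mean PSS-4
  (4-item Perceived Stress Scale, 0–16 after reverse-scoring the
  positively worded items) exceeds 4.7.

## Pipeline

1. **Signal tier** (`nextstress.ecg`): 1-minute windows with 30 s
   overlap; a two-classifier noise screen over 0.6-s intervals (windows
   with >20% noisy intervals dropped) plus a per-second sampling
   reliability check (>0.80 required); Shannon-energy R-peak detection
   (band-pass → Gaussian differentiator → squaring → −s²·log s²
   envelope → refractory peak picking); criterion-beat-difference
   artifact rejection; IBIs restricted to 300–2000 ms.
2. **Feature tier** (`nextstress.hrv`, `nextstress.features`): a
   69-column day table = 30 minute-level HRV statistics averaged per day
   + 17 duration features (consecutive-stress minutes/episodes at 1-, 2-,
   5-, 10-minute minimum run lengths, as counts and percentages, plus a
   binary day-stress flag) + 13 EMA features (12 per-question daily
   means + daily PSS-4) + 4 intervention features + 5 covariates.
3. **Models** (`nextstress.models`, `cfs`, `bayesopt`): six baseline
   classifiers under pooled 5-fold CV; correlation-based feature
   selection maximizing Hall's merit k·r̄cf/√(k + k(k−1)·r̄ff) by
   best-first search over symmetric-uncertainty correlations; Gaussian
   process + expected-improvement tuning of the random forest.
4. **Explainability** (`nextstress.treeshap`, `explain`): exact
   interventional Shapley attributions for tree ensembles (local
   accuracy to machine precision), importance ranking by mean absolute
   attribution with a 0.05 low-importance flag, and dependence data.

`docs/methods.md` documents every model, constant, and design choice.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
synthetic cohort (12 participants × 60 days, strong planted signal) and
write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py    # cohort CSVs + ground truth
python analysis/02_signal_validation.py  # signal tier vs generator truth
python analysis/03_build_features.py     # 69-feature table, labels, pairs
python analysis/04_baseline_models.py    # six baselines + ablation grid
python analysis/05_select_tune.py        # CFS + GP tuning
python analysis/06_explain.py            # exact attributions
```

Output at seed 7:

```
R-peak detection on 2000 clean minutes (159312 beats): F1 0.9993, mean |error| 1.00 ms
end-to-end IBI error (10% noisy minutes): median 1.16 ms over 11552 IBIs; clean windows 86.7%
day table: 720 participant-days x 69 features
physiological pairs: 708 (prevalence 0.771)
perceived pairs: 697 (prevalence 0.439)
[phys] best baseline: support_vector mean F1 0.969 (majority-class F1 0.871)
[perc] best baseline: random_forest mean F1 0.842 (majority-class F1 0.610)
[perc] ablation: EMA-including combos F1 0.834-0.845, EMA-excluding 0.128-0.234
[phys] CFS selected 1 features: binary_stress
[phys] tuned forest -> mean F1 0.963
[perc] tuned forest -> mean F1 0.846
[phys] full-set attribution rank of long-run exposure features:
       {'stress_min_pct_wear_w10': 1, 'episode_pct_w10': 6, ...} (best 1)
[perc] top selected-subset features: ema_pss4_daily (0.185), ema_pss_your_way (0.070), ...
```

Reading: the signal tier recovers beats nearly perfectly against the
generator's truth; both tuned models sit near the planted signal's
ceiling (this seed drew a high stressed-day prevalence, 0.77, so the
always-positive baseline is itself strong on the physiological task —
the perceived task shows the margin more plainly, 0.846 vs 0.610);
removing the EMA channel collapses perceived-stress prediction to far
below baseline while physiological prediction is unaffected (the
planted perceived signal lives only in the EMA channel); and the
attribution ranking recovers the planted dominant predictor —
prior-day long-run (≥10-minute) stress exposure — as the single most
important of all 69 features.

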