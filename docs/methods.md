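# Methods

`nextstress` re-implements, as a tested pipeline over synthetic study
data, an analysis that predicts **next-day stress** — physiological
(sensor-inferred) and perceived (self-reported) — from the prior day's
wearable single-lead ECG, ecological momentary assessments (EMA), and
behavioural-intervention logs in a cohort of pregnant women followed for
about twelve weeks. The original cohort's raw data are not publicly
deposited, so a synthetic study generator with known ground truth stands
in for them; every downstream stage is validated against that truth.

## 1. Signal tier: ECG → interbeat intervals

Raw ECG (nominal 250 Hz) is segmented into **1-minute windows with 30 s
overlap**. Each window is screened for noise in two ways:

* **Interval ensemble.** The window is split into 0.6-s intervals; three
  beat-derived features per interval (detected-peak count, peak-amplitude
  coefficient of variation, high-frequency (>15 Hz) energy ratio) feed an
  ensemble of a margin-based classifier (RBF SVM) and a small feedforward
  network. An interval is called *clean* only when both classifiers
  agree; a window with **>20% noisy intervals is discarded** (strict
  inequality at the boundary). The ensemble is retrainable on the
  generator's noise masks — it is a re-implementation of the published
  two-model screening idea, not a reproduction of any pretrained weights,
  and the three features are this package's documented choice.
* **Reliability.** Per second, the ratio of observed samples to the
  nominal rate; seconds with reliability **≤ 0.80 are discarded**
  (strict inequality: exactly 200 of 250 points fails).

Retained windows pass through Shannon-energy R-peak detection:
band-pass (5–25 Hz, zero-phase) → first-order Gaussian differentiator
(σ = 10 ms) → squaring → Shannon energy −s²·log s² on the normalized
signal → Gaussian envelope smoothing (σ = 40 ms) → local-maximum picking
with a **250 ms refractory period** → refinement to the nearest raw-band
extremum within ±50 ms. The smoothing constants are exposed as arguments;
the cited literature does not pin them, and the defaults were set where
the generator benchmark reaches F1 ≥ 0.99.

Peaks from overlapping windows are merged with a **20 ms deduplication
tolerance**. Artifactual beats are removed by the criterion beat
difference: from the running IBI distribution (rolling window of 51
IBIs), quartile deviation QD, maximal expected difference MED = 3.32·QD,
minimal artifact difference MAD = (median − 2.9·QD)/3, criterion =
(MED + MAD)/2; a beat **both** of whose adjacent IBIs deviate from the
running median by more than the criterion is removed (an inserted beat
splits one plausible interval into two implausible ones), iterating to a
fixed point. Finally, IBIs outside **[300, 2000] ms** — the
operationalisation of the normal human heart-rhythm range — are dropped.

## 2. Feature tier: the 69-column day table

Per valid minute (≥ 2 IBIs), **30 HRV features**: 15 time-domain (mean/
median/min/max IBI, SDNN, RMSSD, SDSD, pNN50, pNN20, CVNN, mean/min/max
HR, HR range, triangular index with 7.8125 ms bins), 7 frequency-domain
(VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.40 Hz band powers via
Lomb–Scargle on the unevenly sampled IBIs, total power, LF/HF, normalized
LF and HF), 4 Poincaré/entropy (SD1, SD2, SD1/SD2, sample entropy with
m = 2, r = 0.2·SDNN, with a +1 continuity guard in both template counts
so regular minutes stay finite), and 4 peak-derived (peak count,
amplitude mean/SD, prominence mean). The full reference feature list of
the original supplement is unavailable; this 30-column set matches the
stated counts and every feature named in the original importance
figures, and its order is frozen.

A margin-based **minute stress classifier** (SVM, grid-searched over
C ∈ {0.1, 1, 10} and linear/RBF kernels on standardized features) is the
retrainable stand-in for the published pretrained minute-level model; it
is trained on a labelled subsample of generator minutes and applied to
all minutes.

From the minute calls, **17 duration features**: for each minimum-run
threshold W ∈ {1, 2, 5, 10} minutes, the total minutes in stress runs of
length ≥ W, the number of such runs (episodes), those minutes as % of
wear time, and those episodes as % of all stress episodes; plus the
day's binary stress indicator. Invalid minutes break runs.

**13 EMA features**: per-question daily means of the 12 items (4 PSS-4
items on 0–4, 8 mood sliders on 0–100) plus the daily mean of the
per-prompt PSS-4 score. PSS-4 uses standard Cohen scoring — the two
positively worded items are reverse-scored — giving a 0–16 range.

**4 intervention features** (prior-day 1:1 indicator, cumulative 1:1
count, prior-day JIT indicator, cumulative JIT count) and **5
covariates** (age, gestational age at enrollment, prior pregnancies,
prior children, EPDS) complete the 30+17+13+4+5 = 69 columns. Missing
blocks stay missing in the table; **median imputation is fitted inside
training folds only**.

## 3. Labels and pairs

A day is physiologically stress positive when stress-positive minutes
exceed **50% of wear minutes** (strict; run threshold 1 minute, i.e. all
stress-positive minutes count; denominator is wear time, consistent with
the duration features being defined over wear). A sensor day needs
≥ 4 h wear to be labelable. A day is perceived stress positive when the
daily mean PSS-4 exceeds **4.7** (strict). Prediction pairs join day t's
features to day t+1's label for calendar-consecutive days with a defined
target; the physiological and perceived tasks keep separate pair sets.

## 4. Models, selection, tuning, attribution

Six baselines with fixed hyperparameters (gradient boosting, RBF SVM,
AdaBoost, Gaussian naive Bayes, decision tree, random forest — the
forest at 10 trees, min split 5, min leaf 2, depth 3) are compared under
**pooled random 5-fold CV** (80/20, all participants mixed — the
replicated protocol; a grouped-by-participant mode exists but is off by
default because pooling lets the model exploit participant identity).
Metrics are positive-class precision, recall, F1 with a
zero-denominator → 0 convention.

**CFS** maximizes Hall's merit k·r̄cf / √(k + k(k−1)·r̄ff) by best-first
search (stop after 5 non-improving expansions), with correlations
measured as symmetric uncertainty on equal-frequency-discretized
(5 bins; NaN its own bin) features. Best-first provably matched
exhaustive search on every random table of ≤ 12 features we generated.
The headline protocol runs CFS once on all pairs before tuning (the
selection-then-tune sequence of the original analysis); a per-fold
selector is available for leakage-free estimates.

**Bayesian optimization** models mean 5-fold F1 as a Gaussian process
(Matérn-5/2 + white noise, normalized outputs) and picks candidates by
expected improvement (ξ = 10⁻⁴; EI scored over the full grid when the
space is small, else over a 512-candidate random pool). The forest space:
n_estimators [10, 400], max_depth [2, 30], min_samples_split [2, 40] on
≤ 200-value grids; criterion {gini, entropy}; max_features
{sqrt, log2, all}.

**Attribution** is exact interventional Shapley for tree ensembles,
computed per (foreground, background) pair from leaf paths: for each
leaf, the features where only the foreground (set A) or only the
background (set B) satisfies the path conditions yield closed-form
weights (|A|−1)!|B|!/(|A|+|B|)! and −|A|!(|B|−1)!/(|A|+|B|)!; features on
which both agree are null players. Averaging over the background gives
local accuracy to machine precision on the probability scale, where the
**0.05 low-importance flag** is applied. The background is a subsample
of the training fold (interventional style); attributions are computed
out-of-fold. A permutation-sampling fallback covers non-tree models.

## 5. The synthetic study generator

The generator emulates the study design: ~12-week cohorts, wear during
waking hours (default **13.0 h/day**, the cohort-table value; the source
also quotes 11.5 h elsewhere, so wear is a free parameter), 5 EMA
prompts/day evenly spaced **inclusive of both endpoints** over waking
hours with 12 questions each, weekly 1:1 sessions (up to 12) each
followed by 4 JIT messages every other day at 19:45, and covariates
drawn to match the published cohort table (age 30–39, gestation 10–17
weeks, 0–2 prior children, EPDS ≈ N(7.2, 3.4) clipped to [0, 30]).
Weekly EMA answer probability peaks in week 2 (0.68) and decays to 0.45,
averaging ≈ 2.9 answered prompts/day.

Minute-level stress is a two-state semi-Markov process with geometric
dwell times; the calm-run mean is derived from the stressed-run mean and
the target stressed fraction so prevalence is controlled exactly.
Stressed minutes have faster, less variable rhythm (IBI 700 ± 35 ms vs
850 ± 60 ms) — the separability the minute classifier needs, asserted
empirically per run. Waveforms superpose a Ricker (Gaussian
second-derivative) QRS template at state-dependent beat times over
baseline wander and sensor noise; a configured fraction of minutes is
replaced by 5× broadband noise and another is dropped. Beat times, noise
masks, state tracks, and latent PSS are all returned, so detectors and
classifiers are scored exactly. Sampling rate defaults to 250 Hz (the
device's rate is not published).

Two day-level signals are planted. **Physiological carryover**:
P(stressed day t+1) = σ(α + β·exposure_t) with exposure = fraction of
wear time in stress runs ≥ 10 min (defaults α = −2.5, β = 9). **Perceived
dynamics**: a latent daily PSS-4 level follows an AR(1) around its mean;
items are generated from it with integer rounding and clipping, and
stressed days can shift PSS by `state_effect`.

`strong_signal_config()` is the validation construct used by the
end-to-end tests and the reproduction script; its values are derived,
not tuned by trial: (i) α = −4, β = 14 makes the next physiological day
~96% determined by exposure; (ii) calm days get 40% stress in ~3-min
runs and stressed days 65% in ~18-min runs, so short-run prevalence
separates the day types only moderately while long-run exposure
separates them sharply — the ≥10-min features are therefore the
*designated dominant predictor* — and both fractions sit far enough from
the 50% threshold that within-day run variance rarely mislabels a day;
(iii) the perceived latent is **anti-persistent** (ρ = −0.97, sd 2.5,
item noise 0.3), a rebound dynamic in which a high-stress day is
reliably followed by a low-stress day. Anti-persistence was chosen
because a persistent latent spends long spells on one side of the fixed
4.7 threshold: across simulated seeds the positive-day prevalence then
ranges ~0.3–0.7 and the always-positive baseline F1 = 2p/(1+p) swallows
the planted margin, whereas the rebound dynamic pins prevalence to
0.48–0.52 at every seed with a Bayes-level accuracy near 0.9. With
`state_effect = 0` the perceived signal lives **only** in the EMA
channel, which is what the feature-type ablation must detect.

### What the generator does not emulate

Real ECG morphology (P/T waves, ectopy, respiration coupling), motion
artifacts with ECG-like structure, EMA item semantics beyond scale and
valence, intervention *effects* on stress (schedules only, unless
configured), circadian structure within the day, and between-day wear
variation. Tests passing on this generator show the pipeline recovers
known structure of this kind; they do not certify performance on real
patch-sensor data.

## 6. Numerical choices and degenerate inputs

Strict inequalities at every published boundary (>20% noise, >80%
reliability, >50% stressed, >4.7 PSS). Recordings shorter than one
window yield an empty grid with a warning; < 3 peaks pass the CBD filter
through unchanged; < 2 IBIs invalidate a minute; zero wear yields
all-zero duration features and an undefined label; single-class training
sets raise errors rather than degrade silently. F1's 0/0 → 0. Sample
entropy uses (A+1)/(B+1) so constant minutes give ≈ 0 instead of NaN.

## 7. Problem sizes

The test suite runs the validation cohort at 12 participants × 60 days
with 6 h wear and 6,000 training minutes for the minute classifier
(≈ 260 k minutes end to end); the signal-tier oracle uses 1,200 minutes.
The reproduction script (`scripts/acceptance.py`) runs the full 13 h wear
condition (≈ 560 k minutes), 10,000 minutes for the R-peak benchmark,
1,000 sequences for the duration oracle, and 200 tables for the CFS
oracle. The analysis scripts use an 8 × 35-day cohort at 8 h wear.

## 8. Known limitations

Pooled CV overstates generalization to new participants (by design, to
replicate the protocol); the 30-feature HRV set and the 17-duration
decomposition are documented reconstructions of unavailable supplementary
tables; the global-CFS headline protocol leaks selection information
across folds (a per-fold mode is provided); the GP optimizer treats the
CV objective as deterministic given the seed; exact attribution cost
grows with foreground × background × leaves, so backgrounds are
subsampled (a few dozen rows).
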