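"""Benchmark the six baseline classifiers and the feature-type ablation.

For each target (physiological, perceived): pooled 5-fold CV of gradient
boosting, SVM, AdaBoost, naive Bayes, decision tree, and random forest on
all 69 features, plus the six feature-type combinations and all-features
with the random forest. Writes cv_results.csv and ablation.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

import nextstress as ns
from _common import RESULTS, SEED, load_pairs


def main() -> None:
    cv_frames, abl_frames = [], []
    for target in ("phys", "perc"):
        pairs = load_pairs(target)
        base = ns.models.majority_baseline_f1(pairs["target"].to_numpy())
        table = ns.pipeline.benchmark_baselines(pairs, seed=SEED)
        table.insert(0, "target", target)
        cv_frames.append(table)
        best = table.iloc[0]
        print(f"[{target}] best baseline: {best['model']} "
              f"mean F1 {best['mean_f1']:.3f} (majority-class F1 {base:.3f})")
        abl = ns.models.feature_group_ablation(pairs, seed=SEED)
        abl.insert(0, "target", target)
        abl_frames.append(abl)
        ema_rows = abl[abl["combination"].str.contains("ema")
                       | (abl["combination"] == "all")]
        non_ema = abl[~abl.index.isin(ema_rows.index)]
        print(f"[{target}] ablation: EMA-including combos F1 "
              f"{ema_rows['mean_f1'].min():.3f}-{ema_rows['mean_f1'].max():.3f}, "
              f"EMA-excluding {non_ema['mean_f1'].min():.3f}-"
              f"{non_ema['mean_f1'].max():.3f}")
    pd.concat(cv_frames).to_csv(RESULTS / "cv_results.csv", index=False)
    pd.concat(abl_frames).to_csv(RESULTS / "ablation.csv", index=False)
    print(f"wrote {RESULTS / 'cv_results.csv'} and {RESULTS / 'ablation.csv'}")


if __name__ == "__main__":
    main()
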