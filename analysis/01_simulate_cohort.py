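"""Simulate the synthetic study cohort and write its CSV bundle.

Generates the multi-week cohort (ECG ground-truth beat series, EMA logs,
intervention schedules, participant covariates, and all planted truth)
and writes the documented CSV schemas under results/cohort/. One day of
one participant is additionally rendered as a raw waveform so the signal
tier has an on-disk example.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import numpy as np

import nextstress as ns
from _common import RESULTS, SEED, build_study, study_config


def main() -> None:
    cfg = study_config()
    import _common
    bundle = ns.synthetic.generate_cohort(_common.N_PARTICIPANTS,
                                          _common.N_DAYS, SEED, cfg)
    out = RESULTS.parent / "scratch" / "cohort"
    ns.io.write_cohort(bundle, out)

    # one rendered waveform day as an on-disk example (large; scratch only)
    rng = np.random.default_rng(SEED)
    key = (bundle.profiles[0].participant_id, bundle.days["date"].iloc[0])
    day = ns.synthetic.render_ecg(bundle.tracks[key], cfg.ecg, rng)
    scratch = RESULTS.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    import pandas as pd
    pd.DataFrame({"timestamp_ms": day.t_ms,
                  "voltage": np.round(day.voltage, 5)}).to_csv(
        scratch / f"ecg_{key[0]}_{key[1]}.csv", index=False)

    n_days = len(bundle.days)
    print(f"cohort: {len(bundle.profiles)} participants x "
          f"{n_days // len(bundle.profiles)} days -> {out}")
    print(f"stressed-day prevalence: {bundle.days['stressed_day'].mean():.3f}")
    print(f"EMA prompts answered: {bundle.ema.groupby(['participant_id', 'date', 'prompt_index']).ngroups} "
          f"({len(bundle.ema)} item responses)")
    print(f"example waveform day written for {key[0]} {key[1]} "
          f"({day.voltage.size} samples)")


if __name__ == "__main__":
    main()
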