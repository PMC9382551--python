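"""Shared settings for the analysis scripts.

One modest cohort, the strong planted-signal configuration, one seed:
every script regenerates or reloads exactly this study so the numbered
steps can be run independently.
"""

from pathlib import Path

import nextstress as ns

SEED = 7
N_PARTICIPANTS = 12
N_DAYS = 60
WEAR_HOURS = 8.0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config():
    cfg = ns.synthetic.strong_signal_config()
    cfg.wear_hours = WEAR_HOURS
    return cfg


def build_study():
    return ns.pipeline.run_study(N_PARTICIPANTS, N_DAYS, SEED,
                                 config=study_config(),
                                 n_train_minutes=6000)


def load_pairs(target: str):
    import pandas as pd

    path = RESULTS / f"pairs_{target}.csv"
    if not path.exists():
        raise SystemExit(
            f"{path} missing - run analysis/03_build_features.py first")
    return pd.read_csv(path)
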