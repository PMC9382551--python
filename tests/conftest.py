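import numpy as np
import pandas as pd
import pytest

import nextstress as ns
from nextstress.features import FEATURE_COLUMNS


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three participants, eight days, default (study-like) configuration."""
    cfg = ns.synthetic.CohortConfig()
    cfg.wear_hours = 2.0
    return ns.synthetic.generate_cohort(3, 8, seed=5, config=cfg)


@pytest.fixture(scope="session")
def tiny_study(tiny_cohort):
    """The study tier run end to end on the tiny cohort."""
    return ns.pipeline.build_study(tiny_cohort, seed=5, n_train_minutes=1500)


@pytest.fixture(scope="session")
def planted_pairs():
    """Tabular pair set with a cleanly separable planted target.

    One feature carries the target (plus small noise), the rest are
    noise; used for model-level tests without the full study tier.
    """
    rng = np.random.default_rng(9)
    n = 300
    X = rng.normal(size=(n, len(FEATURE_COLUMNS)))
    y = (X[:, 40] > 0).astype(int)  # a duration-block column
    X[:, 40] = y + rng.normal(0, 0.05, n)
    pairs = pd.DataFrame(X, columns=FEATURE_COLUMNS)
    pairs.insert(0, "participant_id", [f"P{i % 6}" for i in range(n)])
    pairs.insert(1, "date", "2021-03-01")
    pairs["target"] = y
    return pairs


@pytest.fixture(scope="session")
def e2e_study():
    """The strong-planted-signal validation cohort, end to end.

    12 participants x 60 days with the strong carryover configuration;
    wear hours reduced to keep the suite fast (the planted structure is
    per-minute, so the day-level signal survives the shorter window).
    """
    cfg = ns.synthetic.strong_signal_config()
    cfg.wear_hours = 6.0
    return ns.pipeline.run_study(12, 60, seed=202, config=cfg,
                                 n_train_minutes=6000)


@pytest.fixture(scope="session")
def e2e_tuned(e2e_study):
    """CFS + GP-tuned random forest for both targets of the validation run."""
    out = {}
    for name, pairs in (("phys", e2e_study.pairs_phys),
                        ("perc", e2e_study.pairs_perc)):
        sel, bo, tuned = ns.pipeline.select_and_tune(pairs, seed=202,
                                                     n_iter=25)
        out[name] = {"selected": sel, "bo": bo, "cv": tuned}
    return out
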