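"""Ground-truth day labels and next-day prediction pairs.

A day is *physiologically* stress positive when more than 50% of its wear
minutes are classified stress positive (run threshold 1 minute, i.e. all
stress-positive minutes count), and *perceived* stress positive when the
daily mean PSS-4 exceeds 4.7. Prediction pairs join the feature row of
day t to the labels of the calendar-consecutive day t+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import stress_runs

PHYS_THRESHOLD = 0.50
PERC_THRESHOLD = 4.7
MIN_WEAR_MINUTES = 240  # a sensor day needs >= 4 h of wear to be labelable


def physiological_day_label(minute_calls, wear_minutes: int):
    """(label, stress_minute_fraction); label in {1, 0, None}.

    Positive iff the total stress-positive minutes exceed 50% of wear
    (strict inequality). Undefined when wear is below the 4-hour minimum.
    """
    if wear_minutes is None or wear_minutes < MIN_WEAR_MINUTES:
        return None, np.nan
    minutes = float(stress_runs(minute_calls).sum())
    frac = minutes / wear_minutes
    return int(frac > PHYS_THRESHOLD), frac


def perceived_day_label(pss4_day_mean: float):
    """1 if daily mean PSS-4 > 4.7 (strict), 0 otherwise, None if missing."""
    if pss4_day_mean is None or not np.isfinite(pss4_day_mean):
        return None
    return int(pss4_day_mean > PERC_THRESHOLD)


def build_nextday_pairs(rows: pd.DataFrame, labels: pd.DataFrame,
                        target: str) -> pd.DataFrame:
    """Join day-t feature rows to day-(t+1) labels.

    ``rows`` is the 69-feature day table keyed by participant_id/date;
    ``labels`` carries columns participant_id, date, phys_label,
    perc_label (NaN = undefined). ``target`` is 'phys' or 'perc'.
    A pair is emitted iff the two dates are calendar-consecutive for the
    same participant and the day-(t+1) target is defined.
    """
    if target not in ("phys", "perc"):
        raise ValueError("target must be 'phys' or 'perc'")
    col = f"{target}_label"
    lab = labels[["participant_id", "date", col]].copy()
    lab["date"] = pd.to_datetime(lab["date"])
    feat = rows.copy()
    feat["date"] = pd.to_datetime(feat["date"])
    nxt = lab.copy()
    nxt["date"] = nxt["date"] - pd.Timedelta(days=1)  # align t+1 labels onto day t
    merged = feat.merge(nxt, on=["participant_id", "date"], how="inner",
                        suffixes=("", "_next"))
    merged = merged[merged[col].notna()].reset_index(drop=True)
    merged = merged.rename(columns={col: "target"})
    merged["target"] = merged["target"].astype(int)
    merged["date"] = merged["date"].dt.date.astype(str)
    return merged
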