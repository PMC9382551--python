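"""CSV schemas for cohort data exchange.

ecg/<pid>_<date>.csv      timestamp_ms, voltage
ema.csv                   participant_id, date, prompt_index, time, question_id, response
interventions.csv         participant_id, date, kind, time
participants.csv          one row per participant, covariate columns
truth/                    state tracks, beat times, noise masks (generator only)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg import EcgRecording
from .synthetic import CohortBundle


def write_cohort(bundle: CohortBundle, outdir) -> None:
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "participant_id": p.participant_id,
        "age": p.age,
        "gestational_age_enroll": p.gestational_age_enroll,
        "n_prior_pregnancies": p.n_prior_pregnancies,
        "n_prior_children": p.n_prior_children,
        "epds_score": p.epds_score,
        "wake_time": p.wake_time.isoformat(timespec="minutes"),
        "sleep_time": p.sleep_time.isoformat(timespec="minutes"),
    } for p in bundle.profiles]).to_csv(out / "participants.csv", index=False)
    bundle.ema.to_csv(out / "ema.csv", index=False)
    bundle.interventions[["participant_id", "date", "kind", "time"]].to_csv(
        out / "interventions.csv", index=False)
    bundle.days.to_csv(out / "truth" / "days.csv", index=False)
    track_rows = []
    for (pid, day), track in bundle.tracks.items():
        track_rows.append({
            "participant_id": pid, "date": day,
            "states": "".join("1" if s else "0" for s in track.minute_states),
        })
    pd.DataFrame(track_rows).to_csv(out / "truth" / "state_tracks.csv",
                                    index=False)
    if bundle.ecg:
        (out / "ecg").mkdir(exist_ok=True)
        for (pid, day), rec in bundle.ecg.items():
            pd.DataFrame({"timestamp_ms": rec.t_ms,
                          "voltage": np.round(rec.voltage, 5)}).to_csv(
                out / "ecg" / f"{pid}_{day}.csv", index=False)
            np.savetxt(out / "truth" / f"beats_{pid}_{day}.csv",
                       rec.beat_times_ms, fmt="%.3f",
                       header="beat_time_ms", comments="")


def read_ecg_csv(path, participant_day_id: str,
                 nominal_rate: float) -> EcgRecording:
    df = pd.read_csv(path)
    return EcgRecording(participant_day_id,
                        df["timestamp_ms"].to_numpy(dtype=float),
                        df["voltage"].to_numpy(dtype=float), nominal_rate)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
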