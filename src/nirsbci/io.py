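"""Plain-text file formats: per-trial CSV recordings, label sidecar, YAML config."""
from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .synth import (
    Channel,
    ParticipantProfile,
    ProtocolDesign,
    TrialRecording,
    build_protocol,
    default_profile,
)

_CHANNEL_RE = re.compile(r"^(D\d+)_(S\d+)_(\d+)nm$")


def recording_filename(participant: int, session: int, trial: int) -> str:
    return f"P{participant:02d}_S{session}_T{trial:02d}.csv"


def write_recording(recording: TrialRecording, path: str | Path) -> None:
    """One trial per CSV: time column plus one column per channel."""
    df = pd.DataFrame(recording.data.T, columns=recording.channel_names)
    df.insert(0, "time_s", recording.times)
    df.to_csv(path, index=False, float_format="%.6f")


def read_recording(
    path: str | Path,
    interval_boundaries: Sequence[tuple[int, int]] | None = None,
    participant_id: int = 0,
    session_id: int = 0,
    trial_id: int = 0,
) -> TrialRecording:
    """Read a trial CSV; interval boundaries come from the label sidecar."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected a 'time_s' column plus channel columns")
    times = df["time_s"].to_numpy()
    if len(times) < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    sample_rate = 1.0 / float(np.median(np.diff(times)))
    channels = []
    for name in df.columns[1:]:
        m = _CHANNEL_RE.match(name)
        if not m:
            raise ValueError(f"{path}: channel column {name!r} not in D*_S*_<wl>nm form")
        channels.append(Channel(m.group(1), m.group(2), int(m.group(3))))
    return TrialRecording(
        data=df.iloc[:, 1:].to_numpy().T,
        sample_rate_hz=sample_rate,
        interval_boundaries=[tuple(b) for b in (interval_boundaries or [])],
        channels=channels,
        participant_id=participant_id,
        session_id=session_id,
        trial_id=trial_id,
    )


def write_label_table(label_table: pd.DataFrame, path: str | Path) -> None:
    label_table.to_csv(path, index=False)


def read_label_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant", "session", "trial", "interval_index",
                "class", "start_sample", "end_sample"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: label table is missing columns {sorted(missing)}")
    return df


def write_study(
    recordings: Sequence[TrialRecording],
    label_table: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write every trial CSV plus labels.csv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(
            rec, out / recording_filename(rec.participant_id, rec.session_id, rec.trial_id)
        )
    write_label_table(label_table, out / "labels.csv")
    return out


def read_study(data_dir: str | Path) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Read a study directory written by :func:`write_study`."""
    data_dir = Path(data_dir)
    label_table = read_label_table(data_dir / "labels.csv")
    recordings = []
    for (p, s, t), grp in label_table.groupby(["participant", "session", "trial"]):
        path = data_dir / recording_filename(int(p), int(s), int(t))
        if not path.exists():
            raise ValueError(f"missing recording file {path} referenced by label table")
        bounds = [
            (int(r["start_sample"]), int(r["end_sample"]))
            for _, r in grp.sort_values("interval_index").iterrows()
        ]
        recordings.append(
            read_recording(path, bounds, participant_id=int(p),
                           session_id=int(s), trial_id=int(t))
        )
    return recordings, label_table


def load_study_config(path: str | Path) -> dict:
    """Parse a YAML study configuration into protocol + profiles + seed."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    proto_cfg = raw.get("protocol", {})
    protocol = build_protocol(
        sessions=proto_cfg.get("sessions", 3),
        trials_per_session=proto_cfg.get("trials_per_session", 32),
        seed=proto_cfg.get("seed", raw.get("seed", 0)),
    )
    profiles = []
    if "participants" in raw:
        for i, pcfg in enumerate(raw["participants"]):
            pcfg = dict(pcfg)
            if "effect_slope" in pcfg:
                pcfg["effect_slope"] = {
                    k: np.asarray(v, dtype=float) for k, v in pcfg["effect_slope"].items()
                }
                profiles.append(ParticipantProfile(participant_id=i, **pcfg))
            else:
                profiles.append(default_profile(participant_id=i, **pcfg))
    else:
        n = raw.get("n_participants", 1)
        for i in range(n):
            profiles.append(default_profile(participant_id=i, seed=raw.get("seed", 0) + i))
    return {"protocol": protocol, "profiles": profiles, "seed": raw.get("seed", 0)}
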