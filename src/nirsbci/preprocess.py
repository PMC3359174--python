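"""Trial preprocessing: normalize, detrend, segment, low-pass filter.

Pipeline order follows the analysis protocol: per-trial channel
standardization and linear detrending on the whole trial, extraction of the
three 20 s system-vigilant segments, then zero-phase low-pass filtering of
each segment with a 3rd-order Chebyshev type II design (cut-off 0.1 Hz,
stop 0.5 Hz, <=6 dB passband loss, >=50 dB stopband attenuation) to
suppress respiratory, cardiac and Mayer-wave oscillations.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .synth import TrialRecording, CLASSES


@dataclass(frozen=True)
class FilterSpec:
    """Specification of the preprocessing low-pass filter."""

    order: int = 3
    cutoff_hz: float = 0.1
    stop_hz: float = 0.5
    max_passband_loss_db: float = 6.0
    min_stopband_atten_db: float = 50.0
    sample_rate_hz: float = 31.25

    def validate(self) -> None:
        if min(self.cutoff_hz, self.stop_hz, self.sample_rate_hz,
               self.max_passband_loss_db, self.min_stopband_atten_db) <= 0:
            raise ValueError("all filter magnitudes must be positive")
        if not (self.cutoff_hz < self.stop_hz < self.sample_rate_hz / 2):
            raise ValueError("need cutoff_hz < stop_hz < Nyquist frequency")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass(eq=False)
class SegmentSample:
    """One labelled, preprocessed 20 s system-vigilant segment."""

    data: np.ndarray  # (channels, samples)
    label: str
    participant: int = 0
    session: int = 0
    trial: int = 0
    interval_index: int = 0


def normalize_trial(recording: TrialRecording) -> TrialRecording:
    """Standardize each channel by its own whole-trial mean and sd.

    Removes inter-trial differences in optode coupling (the headband is
    re-seated between trials in the real experiment). A zero-variance
    channel signals a dead sensor and is rejected by name.
    """
    data = recording.data
    if data.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel to normalize")
    sd = data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [recording.channel_names[i] for i in dead]
        raise ValueError(f"zero-variance (dead) channel(s): {', '.join(names)}")
    out = (data - data.mean(axis=1, keepdims=True)) / sd[:, None]
    return dataclasses.replace(recording, data=out)


def detrend_trial(recording: TrialRecording) -> TrialRecording:
    """Remove the per-channel least-squares line (instrument drift)."""
    if recording.data.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel to detrend")
    out = signal.detrend(recording.data, axis=1, type="linear")
    return dataclasses.replace(recording, data=out)


def design_lowpass(spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Design the Chebyshev II low-pass as second-order sections.

    The design places exactly ``min_stopband_atten_db`` of attenuation at
    the stop edge; the passband-loss constraint is then verified on a dense
    frequency grid and a violation is reported as unachievable at this
    order. The cascaded (SOS) form is used for numerical robustness at this
    narrow relative band (0.1 Hz cut-off at 31.25 Hz sampling).
    """
    spec.validate()
    sos = signal.cheby2(
        spec.order,
        spec.min_stopband_atten_db,
        spec.stop_hz,
        btype="lowpass",
        fs=spec.sample_rate_hz,
        output="sos",
    )
    w, h = signal.sosfreqz(sos, worN=8192, fs=spec.sample_rate_hz)
    mag_db = 20 * np.log10(np.maximum(np.abs(h), 1e-300))
    passband = w <= spec.cutoff_hz
    if np.any(-mag_db[passband] > spec.max_passband_loss_db):
        worst = float((-mag_db[passband]).max())
        raise ValueError(
            f"passband constraint unachievable at order {spec.order}: loss reaches "
            f"{worst:.2f} dB <= {spec.cutoff_hz} Hz (limit {spec.max_passband_loss_db} dB)"
        )
    stopband = w >= spec.stop_hz
    if np.any(-mag_db[stopband] < spec.min_stopband_atten_db - 1e-6):
        worst = float((-mag_db[stopband]).min())
        raise ValueError(
            f"stopband constraint unachievable at order {spec.order}: attenuation falls to "
            f"{worst:.2f} dB >= {spec.stop_hz} Hz (limit {spec.min_stopband_atten_db} dB)"
        )
    return sos


def filter_response_db(sos: np.ndarray, freqs_hz, sample_rate_hz: float = 31.25) -> np.ndarray:
    """Magnitude response in dB at the given frequencies."""
    w, h = signal.sosfreqz(sos, worN=np.asarray(freqs_hz, dtype=float), fs=sample_rate_hz)
    return 20 * np.log10(np.maximum(np.abs(h), 1e-300))


def extract_segments(
    recording: TrialRecording, labels: Sequence[str]
) -> list[SegmentSample]:
    """Cut the labelled vigilant periods out of a (whole-trial) recording."""
    labels = list(labels)
    if len(labels) != len(recording.interval_boundaries):
        raise ValueError(
            f"got {len(labels)} labels for {len(recording.interval_boundaries)} intervals"
        )
    for lab in labels:
        if lab not in CLASSES:
            raise ValueError(f"unknown class label {lab!r}")
    segments = []
    for k, ((start, end), lab) in enumerate(zip(recording.interval_boundaries, labels)):
        if not (0 <= start < end <= recording.n_samples):
            raise ValueError(
                f"interval {k} boundary ({start}, {end}) outside recording of "
                f"{recording.n_samples} samples"
            )
        segments.append(
            SegmentSample(
                data=recording.data[:, start:end].copy(),
                label=lab,
                participant=recording.participant_id,
                session=recording.session_id,
                trial=recording.trial_id,
                interval_index=k,
            )
        )
    return segments


def filter_segment(segment: SegmentSample, sos: np.ndarray) -> SegmentSample:
    """Zero-phase (forward-backward) low-pass filtering of one segment.

    Forward-backward application avoids the several-second group delay a
    causal 0.1 Hz filter would impose on a 20 s window. Edge transients are
    handled by odd-reflection padding of one full segment length — a 0.1 Hz
    filter settles over tens of seconds, so the default short padding would
    leak transients across the whole 20 s window.
    """
    n = segment.data.shape[1]
    out = signal.sosfiltfilt(sos, segment.data, axis=1, padlen=max(n - 2, 0))
    return dataclasses.replace(segment, data=np.ascontiguousarray(out))


def preprocess_trial(
    recording: TrialRecording,
    labels: Sequence[str],
    sos: np.ndarray,
) -> list[SegmentSample]:
    """normalize -> detrend -> extract -> filter for one trial."""
    rec = detrend_trial(normalize_trial(recording))
    return [filter_segment(seg, sos) for seg in extract_segments(rec, labels)]


def preprocess_study(
    recordings: Sequence[TrialRecording],
    label_table: pd.DataFrame,
    spec: FilterSpec = FilterSpec(),
) -> list[SegmentSample]:
    """Preprocess every recording of a study using its label sidecar."""
    sos = design_lowpass(spec)
    by_trial = {}
    for _, row in label_table.iterrows():
        key = (row["participant"], row["session"], row["trial"])
        by_trial.setdefault(key, {})[int(row["interval_index"])] = row["class"]
    segments: list[SegmentSample] = []
    for rec in recordings:
        key = (rec.participant_id, rec.session_id, rec.trial_id)
        if key not in by_trial:
            raise ValueError(f"no labels for trial {key} in label table")
        lab_map = by_trial[key]
        labels = [lab_map[k] for k in sorted(lab_map)]
        segments.extend(preprocess_trial(rec, labels, sos))
    return segments
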