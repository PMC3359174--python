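"""Multi-window regression-slope feature extraction.

Each preprocessed 20 s segment is summarized by the ordinary-least-squares
slope of every channel over ten time windows — all (start, end) pairs with
start in {0, 5, 10, 15} s, end in {5, 10, 15, 20} s and end > start —
yielding an 18 x 10 = 180-dimensional feature vector per segment. Slopes
capture the task-evoked amplitude drift of the haemodynamic response while
the window grid accommodates inter-individual differences in response
timing.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .preprocess import SegmentSample


class TimeWindow(NamedTuple):
    start_s: float
    end_s: float


def enumerate_windows(
    duration_s: float = 20.0, step_s: float = 5.0
) -> list[TimeWindow]:
    """All valid windows on the 5 s grid, in (start, end) lexicographic order."""
    starts = np.arange(0.0, duration_s, step_s)
    ends = np.arange(step_s, duration_s + step_s / 2, step_s)
    return [
        TimeWindow(float(s), float(e)) for s in starts for e in ends if e > s
    ]


def window_slice(window: TimeWindow, sample_rate_hz: float) -> slice:
    """Half-open sample range [floor(start*fs), floor(end*fs))."""
    lo = int(np.floor(window.start_s * sample_rate_hz))
    hi = int(np.floor(window.end_s * sample_rate_hz))
    return slice(lo, hi)


def compute_slope(
    series: np.ndarray, window: TimeWindow, sample_rate_hz: float
) -> float:
    """OLS slope (units per second) of one channel over one window."""
    if window.end_s <= window.start_s:
        raise ValueError(f"empty window {window}")
    sl = window_slice(window, sample_rate_hz)
    y = np.asarray(series, dtype=float)[sl]
    if y.size < 2:
        raise ValueError(
            f"window {window} covers {y.size} sample(s); need at least 2"
        )
    t = (np.arange(sl.start, sl.stop) / sample_rate_hz)
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


@dataclass(eq=False)
class FeatureMatrix:
    """Segments x (channel, window) slope features with provenance."""

    values: np.ndarray  # (n_segments, n_channels * n_windows)
    columns: list[tuple[int, TimeWindow]]  # (channel index, window) per column
    labels: np.ndarray  # class label per row
    meta: pd.DataFrame  # per-row provenance: participant, session, trial, interval

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def build_feature_matrix(
    segments: Sequence[SegmentSample],
    sample_rate_hz: float = 31.25,
    windows: Sequence[TimeWindow] | None = None,
) -> FeatureMatrix:
    """Slope features for every (segment, channel, window) combination.

    Columns are ordered channel-major: channel 0's ten windows first, then
    channel 1's, and so on — a stable, deterministic layout.
    """
    if not segments:
        raise ValueError("no segments supplied")
    if windows is None:
        windows = enumerate_windows()
    n_ch, n_samp = segments[0].data.shape
    for seg in segments:
        if seg.data.shape != (n_ch, n_samp):
            raise ValueError("all segments must share channel count and duration")
    stack = np.stack([seg.data for seg in segments])  # (n_seg, n_ch, n_samp)
    n_seg = stack.shape[0]
    n_win = len(windows)
    slopes = np.empty((n_seg, n_ch, n_win))
    for w, win in enumerate(windows):
        sl = window_slice(win, sample_rate_hz)
        if sl.stop - sl.start < 2:
            raise ValueError(f"window {win} covers fewer than 2 samples")
        if sl.stop > n_samp:
            raise ValueError(f"window {win} extends past the {n_samp}-sample segment")
        t = np.arange(sl.start, sl.stop) / sample_rate_hz
        tc = t - t.mean()
        y = stack[:, :, sl]
        slopes[:, :, w] = (y - y.mean(axis=2, keepdims=True)) @ tc / (tc @ tc)
    values = slopes.reshape(n_seg, n_ch * n_win)
    columns = [(c, win) for c in range(n_ch) for win in windows]
    labels = np.array([seg.label for seg in segments])
    meta = pd.DataFrame(
        {
            "participant": [s.participant for s in segments],
            "session": [s.session for s in segments],
            "trial": [s.trial for s in segments],
            "interval_index": [s.interval_index for s in segments],
            "class": labels,
        }
    )
    return FeatureMatrix(values=values, columns=columns, labels=labels, meta=meta)
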