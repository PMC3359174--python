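"""Synthetic fNIRS study generator.

Emulates a system-paced near-infrared spectroscopy brain-computer-interface
experiment: a participant answers multiple-choice questions by entering an
intentional-control state — mental arithmetic (MA) or mental singing (MS) —
during 20 s "system-vigilant" periods, or stays in the no-control (NC) state.
Light intensity is recorded on 18 channels (3 detectors x 3 source-pairs per
detector x 2 wavelengths, all at 3 cm source-detector separation) at 31.25 Hz.

The generator plants the statistical structure the downstream analysis
assumes: a class-dependent amplitude drift (ramp) during task performance,
superimposed on Mayer-wave (~0.1 Hz), respiratory (0.2-0.3 Hz) and cardiac
(0.8-1.2 Hz) oscillations, instrument drift, white sensor noise, and
per-trial optode-coupling gain/offset perturbations.
"""
from __future__ import annotations

import dataclasses
import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CLASSES = ("MA", "MS", "NC")
IC_CLASSES = ("MA", "MS")
WAVELENGTHS_NM = (690, 830)

DEFAULT_SAMPLE_RATE_HZ = 31.25
DEFAULT_VIGILANT_S = 20.0
DEFAULT_SEPARATION_S = 12.0
DEFAULT_SEPARATION_CM = 3.0
N_CHANNELS = 18


# --------------------------------------------------------------------------
# Optode geometry and channel enumeration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    """One light path: (detector, source-pair, wavelength)."""

    detector: str
    source_pair: str
    wavelength_nm: int

    @property
    def name(self) -> str:
        return f"{self.detector}_{self.source_pair}_{self.wavelength_nm}nm"


@dataclass(frozen=True)
class OptodeGeometry:
    """Planar optode layout in centimetres on the forehead.

    Each source-pair position carries one source per wavelength, so every
    qualifying (detector, source-pair) combination yields two channels.
    """

    detectors: Mapping[str, tuple[float, float]]
    source_pairs: Mapping[str, tuple[float, float]]
    wavelengths_nm: tuple[int, ...] = WAVELENGTHS_NM


def _circle_intersections(a, b, r):
    """The two points at distance ``r`` from both ``a`` and ``b``."""
    ax, ay = a
    bx, by = b
    d = math.hypot(bx - ax, by - ay)
    if d == 0 or d > 2 * r:
        raise ValueError("circles do not intersect")
    mx, my = (ax + bx) / 2, (ay + by) / 2
    h = math.sqrt(r * r - (d / 2) ** 2)
    ux, uy = (bx - ax) / d, (by - ay) / d
    return (mx - h * uy, my + h * ux), (mx + h * uy, my - h * ux)


def default_geometry() -> OptodeGeometry:
    """Trapezoidal 9-point frontal layout: 3 detectors, 5 source-pairs.

    Constructed so each detector sees exactly three source-pairs at 3 cm,
    giving 9 interrogation points and 18 channels over two wavelengths.
    """
    detectors = {"D1": (-1.5, 0.0), "D2": (1.5, 0.0), "D3": (0.0, 4.5)}
    y1 = math.sqrt(9.0 - 1.5 ** 2)
    p, q = _circle_intersections(detectors["D1"], detectors["D3"], 3.0)
    s3 = min((p, q), key=lambda xy: xy[0])  # outer (negative-x) solution
    s4 = (-s3[0], s3[1])
    source_pairs = {
        "S1": (0.0, y1),
        "S2": (0.0, -y1),
        "S3": s3,
        "S4": s4,
        "S5": (0.0, 7.5),
    }
    return OptodeGeometry(detectors=detectors, source_pairs=source_pairs)


def enumerate_channels(
    geometry: OptodeGeometry,
    separation_cm: float = DEFAULT_SEPARATION_CM,
    tol_cm: float = 0.01,
) -> list[Channel]:
    """All channels whose source-detector separation is ``separation_cm``.

    Only 3 cm paths (the accepted depth for cortical haemodynamics) are kept
    by default. ``tol_cm`` is the allowed deviation; a tiny relative epsilon
    is always included so exactly-constructed layouts survive ``tol_cm=0``.
    """
    if not geometry.detectors or not geometry.source_pairs:
        raise ValueError("empty optode geometry: need at least one detector and one source-pair")
    eps = tol_cm + 1e-9 * max(separation_cm, 1.0)
    channels: list[Channel] = []
    for det in sorted(geometry.detectors):
        dx, dy = geometry.detectors[det]
        for src in sorted(geometry.source_pairs):
            sx, sy = geometry.source_pairs[src]
            if abs(math.hypot(sx - dx, sy - dy) - separation_cm) <= eps:
                for wl in geometry.wavelengths_nm:
                    channels.append(Channel(det, src, wl))
    if not channels:
        raise ValueError(
            f"no source-detector pair lies at the {separation_cm} cm separation "
            f"(tolerance {tol_cm} cm); cannot form any channel"
        )
    return channels


# --------------------------------------------------------------------------
# Protocol design
# --------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class ProtocolDesign:
    """Study layout: per (session, trial, vigilant interval) class labels."""

    labels: np.ndarray  # (sessions, trials_per_session, intervals) of {MA, MS, NC}
    sessions: int
    trials_per_session: int
    intervals_per_trial: int = 3
    vigilant_duration_s: float = DEFAULT_VIGILANT_S
    separation_duration_s: float = DEFAULT_SEPARATION_S

    @property
    def n_trials(self) -> int:
        return self.sessions * self.trials_per_session

    @property
    def n_segments(self) -> int:
        return self.n_trials * self.intervals_per_trial

    def label_counts(self) -> dict[str, int]:
        flat = self.labels.ravel()
        return {c: int((flat == c).sum()) for c in CLASSES}


# The 8 answer-combination patterns over 3 highlighted choices: which of the
# three vigilant intervals are intentional-control (answer selected).
_PATTERNS = [p for p in itertools.product((False, True), repeat=3)]
_EMPTY_PATTERN = _PATTERNS.index((False, False, False))

# Task assignments over one set of the 8 patterns: exactly 4 trials are MA
# and 4 are MS, with the MA trials covering exactly half (6) of the 12 IC
# intervals — so IC periods split evenly between the tasks. The all-NC
# pattern trial carries a task cue but contributes no IC interval; splits
# are partitioned by which task receives it so that alternating between the
# two groups across sets also balances the count of trials that *show* each
# task.
_SPLITS_EMPTY_TO_MA = []
_SPLITS_EMPTY_TO_MS = []
for _ma in itertools.combinations(range(8), 4):
    if sum(sum(_PATTERNS[i]) for i in _ma) == 6:
        (_SPLITS_EMPTY_TO_MA if _EMPTY_PATTERN in _ma else _SPLITS_EMPTY_TO_MS).append(_ma)


def build_protocol(
    sessions: int = 3,
    trials_per_session: int = 32,
    seed: int | None = 0,
    vigilant_duration_s: float = DEFAULT_VIGILANT_S,
    separation_duration_s: float = DEFAULT_SEPARATION_S,
) -> ProtocolDesign:
    """Randomized but balanced study protocol.

    Each session holds ``trials_per_session / 8`` complete sets of the eight
    answer-combination patterns; within every set four trials are mental
    arithmetic and four mental singing, covering six IC intervals each. At
    the defaults (3 sessions x 32 trials) this yields exactly 72 MA, 72 MS
    and 144 NC vigilant periods. Trial order is shuffled per session.
    """
    if sessions < 1 or trials_per_session < 1:
        raise ValueError("sessions and trials_per_session must be positive")
    if trials_per_session % 8 != 0:
        raise ValueError(
            "trials_per_session must be divisible by 8 so that each of the eight "
            f"answer-combination patterns occurs equally often (got {trials_per_session})"
        )
    rng = np.random.default_rng(seed)
    n_sets = trials_per_session // 8
    labels = np.empty((sessions, trials_per_session, 3), dtype="<U2")
    set_counter = 0
    for s in range(sessions):
        trials: list[list[str]] = []
        for _ in range(n_sets):
            pool = _SPLITS_EMPTY_TO_MA if set_counter % 2 else _SPLITS_EMPTY_TO_MS
            set_counter += 1
            ma_set = pool[rng.integers(len(pool))]
            for i, pattern in enumerate(_PATTERNS):
                task = "MA" if i in ma_set else "MS"
                trials.append([task if ic else "NC" for ic in pattern])
        order = rng.permutation(len(trials))
        for t, j in enumerate(order):
            labels[s, t] = trials[j]
    return ProtocolDesign(
        labels=labels,
        sessions=sessions,
        trials_per_session=trials_per_session,
        vigilant_duration_s=vigilant_duration_s,
        separation_duration_s=separation_duration_s,
    )


# --------------------------------------------------------------------------
# Participant profiles
# --------------------------------------------------------------------------

@dataclass
class ParticipantProfile:
    """Signal-model parameters for one simulated participant.

    ``effect_slope`` maps each intentional-control class to a per-channel
    slope (raw-intensity units per second) of the task-evoked amplitude
    drift; the no-control state has no evoked component. A participant with
    ``ms_responder=False`` produces no consistent response to mental singing
    (MS slopes are all zero), mirroring users for whom that task is
    ineffective.
    """

    effect_slope: dict[str, np.ndarray] = field(
        default_factory=lambda: {c: np.zeros(N_CHANNELS) for c in IC_CLASSES}
    )
    effect_onset_s: float = 2.0
    ms_responder: bool = True
    noise_amp_mayer: float = 1.0
    noise_amp_resp: float = 0.6
    noise_amp_cardiac: float = 0.4
    noise_freq_mayer: float = 0.1
    noise_freq_resp: float = 0.25
    noise_freq_cardiac: float = 1.0
    drift_slope: float = 0.02
    white_noise_sd: float = 0.3
    coupling_gain_sd: float = 0.05
    coupling_offset_sd: float = 2.0
    baseline: float = 100.0
    relax_tau_s: float = 6.0
    n_channels: int = N_CHANNELS
    participant_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for c in IC_CLASSES:
            self.effect_slope[c] = np.asarray(self.effect_slope[c], dtype=float)
            if self.effect_slope[c].shape != (self.n_channels,):
                raise ValueError(f"effect_slope[{c!r}] must have shape ({self.n_channels},)")
        self.validate()

    def validate(self) -> None:
        if not (0.2 <= self.noise_freq_resp <= 0.3):
            raise ValueError("respiration frequency must lie in [0.2, 0.3] Hz")
        if not (0.8 <= self.noise_freq_cardiac <= 1.2):
            raise ValueError("cardiac frequency must lie in [0.8, 1.2] Hz")
        if not (0.05 <= self.noise_freq_mayer <= 0.15):
            raise ValueError("Mayer-wave frequency must lie near 0.1 Hz ([0.05, 0.15])")
        if not self.ms_responder and np.any(self.effect_slope["MS"] != 0.0):
            raise ValueError("a non-responder profile must have zero MS effect slopes")
        for name in ("noise_amp_mayer", "noise_amp_resp", "noise_amp_cardiac",
                     "white_noise_sd", "coupling_gain_sd", "coupling_offset_sd",
                     "relax_tau_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def null_copy(self) -> "ParticipantProfile":
        """Same noise model with all task effects removed."""
        return dataclasses.replace(
            self,
            effect_slope={c: np.zeros(self.n_channels) for c in IC_CLASSES},
        )


# --------------------------------------------------------------------------
# Trial and study simulation
# --------------------------------------------------------------------------

@dataclass(eq=False)
class TrialRecording:
    """One trial's multichannel raw light-intensity time series."""

    data: np.ndarray  # (channels, samples)
    sample_rate_hz: float
    interval_boundaries: list[tuple[int, int]]  # (start, end) sample of each vigilant period
    channels: list[Channel]
    participant_id: int = 0
    session_id: int = 0
    trial_id: int = 0

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


def trial_timing(
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    vigilant_duration_s: float = DEFAULT_VIGILANT_S,
    separation_duration_s: float = DEFAULT_SEPARATION_S,
    intervals: int = 3,
) -> tuple[int, list[tuple[int, int]]]:
    """Total sample count and vigilant-interval boundaries for one trial.

    A trial is laid out as [separation, vigilant] x 3 (96 s at defaults), so
    every vigilant period is preceded by a 12 s recovery window.
    """
    if sample_rate_hz <= 0 or vigilant_duration_s <= 0 or separation_duration_s < 0:
        raise ValueError("sample rate and durations must be positive")
    n_sep = int(round(separation_duration_s * sample_rate_hz))
    n_vig = int(round(vigilant_duration_s * sample_rate_hz))
    boundaries = []
    pos = 0
    for _ in range(intervals):
        pos += n_sep
        boundaries.append((pos, pos + n_vig))
        pos += n_vig
    return pos, boundaries


def simulate_trial(
    profile: ParticipantProfile,
    trial_labels: Sequence[str],
    seed: int | None = None,
    *,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    vigilant_duration_s: float = DEFAULT_VIGILANT_S,
    separation_duration_s: float = DEFAULT_SEPARATION_S,
    channels: list[Channel] | None = None,
    participant_id: int | None = None,
    session_id: int = 0,
    trial_id: int = 0,
) -> TrialRecording:
    """Synthesize one trial.

    Per channel the signal is
    ``baseline + drift*t + offset + gain * (oscillatory noise + white noise
    + task component)``, where the task component during a vigilant interval
    labelled ``c`` is a linear ramp of slope ``effect_slope[c]`` starting
    ``effect_onset_s`` after interval onset, relaxing back toward baseline
    with time constant ``relax_tau_s`` once the interval ends. Coupling gain
    and offset are redrawn per trial; oscillation phases are redrawn per
    trial per component.
    """
    labels = list(trial_labels)
    for lab in labels:
        if lab not in CLASSES:
            raise ValueError(f"unknown class label {lab!r}; expected one of {CLASSES}")
    n, boundaries = trial_timing(
        sample_rate_hz, vigilant_duration_s, separation_duration_s, intervals=len(labels)
    )
    rng = np.random.default_rng(seed)
    nch = profile.n_channels
    t = np.arange(n) / sample_rate_hz

    gain = 1.0 + rng.normal(0.0, profile.coupling_gain_sd)
    offset = rng.normal(0.0, profile.coupling_offset_sd)
    phases = rng.uniform(0.0, 2 * np.pi, size=3)
    white = rng.normal(0.0, 1.0, size=(nch, n)) * profile.white_noise_sd

    osc = np.zeros(n)
    for amp, freq, ph in zip(
        (profile.noise_amp_mayer, profile.noise_amp_resp, profile.noise_amp_cardiac),
        (profile.noise_freq_mayer, profile.noise_freq_resp, profile.noise_freq_cardiac),
        phases,
    ):
        if amp > 0:
            osc += amp * np.sin(2 * np.pi * freq * t + ph)

    task = np.zeros((nch, n))
    onset = profile.effect_onset_s
    for (start, end), lab in zip(boundaries, labels):
        if lab == "NC":
            continue
        slopes = profile.effect_slope[lab]
        if not np.any(slopes):
            continue
        t0 = start / sample_rate_hz + onset
        t_end = end / sample_rate_hz
        rise = (t >= t0) & (t < t_end)
        task[:, rise] += slopes[:, None] * (t[rise] - t0)[None, :]
        peak = max(vigilant_duration_s - onset, 0.0)
        if peak > 0:
            after = t >= t_end
            if profile.relax_tau_s > 0:
                decay = np.exp(-(t[after] - t_end) / profile.relax_tau_s)
            else:
                decay = np.zeros(after.sum())
            task[:, after] += slopes[:, None] * peak * decay[None, :]

    data = (
        profile.baseline
        + profile.drift_slope * t[None, :]
        + offset
        + gain * (osc[None, :] + white + task)
    )
    if channels is None:
        channels = enumerate_channels(default_geometry())[:nch]
    return TrialRecording(
        data=data,
        sample_rate_hz=sample_rate_hz,
        interval_boundaries=boundaries,
        channels=channels,
        participant_id=profile.participant_id if participant_id is None else participant_id,
        session_id=session_id,
        trial_id=trial_id,
    )


def simulate_study(
    profiles: Sequence[ParticipantProfile],
    protocol: ProtocolDesign,
    seed: int | None = 0,
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """One recording per (participant, session, trial) plus the label table.

    The label table has one row per vigilant segment with columns
    participant, session, trial, interval_index, class, start_sample,
    end_sample — the sidecar format consumed by the preprocessing stage.
    """
    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(
        0, 2**31 - 1,
        size=(len(profiles), protocol.sessions, protocol.trials_per_session),
    )
    channels = None
    recordings: list[TrialRecording] = []
    rows = []
    for p, profile in enumerate(profiles):
        for s in range(protocol.sessions):
            for tr in range(protocol.trials_per_session):
                labels = protocol.labels[s, tr]
                rec = simulate_trial(
                    profile,
                    labels,
                    seed=int(trial_seeds[p, s, tr]),
                    sample_rate_hz=DEFAULT_SAMPLE_RATE_HZ,
                    vigilant_duration_s=protocol.vigilant_duration_s,
                    separation_duration_s=protocol.separation_duration_s,
                    channels=channels,
                    participant_id=p,
                    session_id=s,
                    trial_id=tr,
                )
                channels = rec.channels
                recordings.append(rec)
                for k, (a, b) in enumerate(rec.interval_boundaries):
                    rows.append((p, s, tr, k, labels[k], a, b))
    label_table = pd.DataFrame(
        rows,
        columns=["participant", "session", "trial", "interval_index",
                 "class", "start_sample", "end_sample"],
    )
    return recordings, label_table


# --------------------------------------------------------------------------
# Calibrated default profiles
# --------------------------------------------------------------------------

def estimate_noise_slope_sd(
    profile: ParticipantProfile, n_trials: int = 6, seed: int = 0
) -> tuple[float, float]:
    """(slope sd, raw-signal sd) of the profile's task-free noise.

    Simulates all-NC trials, runs the standard preprocessing (normalize,
    detrend, segment, low-pass), and returns the standard deviation of the
    full-window regression slope across segments and channels — the
    noise-induced slope scale against which planted effects are sized — plus
    the mean per-channel raw standard deviation of the null trials (the
    scale by which per-trial normalization divides).
    """
    from .preprocess import FilterSpec, design_lowpass, preprocess_trial
    from .features import TimeWindow, compute_slope

    null = profile.null_copy()
    sos = design_lowpass(FilterSpec())
    window = TimeWindow(0.0, DEFAULT_VIGILANT_S)
    slopes = []
    raw_sds = []
    for i in range(n_trials):
        rec = simulate_trial(null, ("NC", "NC", "NC"), seed=seed * 1000 + i)
        raw_sds.append(rec.data.std(axis=1).mean())
        for seg in preprocess_trial(rec, ("NC", "NC", "NC"), sos):
            for ch in range(seg.data.shape[0]):
                slopes.append(compute_slope(seg.data[ch], window, rec.sample_rate_hz))
    return float(np.std(slopes)), float(np.mean(raw_sds))


def default_profile(
    participant_id: int = 0,
    ms_responder: bool = True,
    seed: int = 0,
    effect_snr: float = 2.5,
    n_responsive: int = 6,
    **overrides,
) -> ParticipantProfile:
    """A calibrated participant: planted effects sized relative to noise.

    Effect slopes are planted on ``n_responsive`` randomly chosen channels
    per intentional-control class with random signs (the two wavelengths of
    a location trend oppositely in real optical data, so signs are free).
    The magnitude is ``effect_snr`` times the noise-induced slope standard
    deviation measured on this profile's own task-free signal, expressed
    back in raw-intensity units via the null trials' raw scale.
    """
    rng = np.random.default_rng(seed)
    resp_f = rng.uniform(0.2, 0.3)
    card_f = rng.uniform(0.8, 1.2)
    base = ParticipantProfile(
        noise_freq_resp=resp_f,
        noise_freq_cardiac=card_f,
        ms_responder=ms_responder,
        participant_id=participant_id,
        seed=seed,
        **overrides,
    )
    slope_sd, raw_sd = estimate_noise_slope_sd(base, seed=seed)
    magnitude = effect_snr * slope_sd * raw_sd
    effect = {c: np.zeros(base.n_channels) for c in IC_CLASSES}
    active_classes = IC_CLASSES if ms_responder else ("MA",)
    for c in active_classes:
        idx = rng.choice(base.n_channels, size=n_responsive, replace=False)
        signs = rng.choice((-1.0, 1.0), size=n_responsive)
        effect[c][idx] = signs * magnitude
    base.effect_slope = effect
    base.__post_init__()
    return base


def default_study_profiles(
    n_participants: int = 7, n_ms_responders: int = 4, seed: int = 0
) -> list[ParticipantProfile]:
    """Default simulated cohort: 7 participants, 4 of whom respond to MS."""
    return [
        default_profile(
            participant_id=p,
            ms_responder=p < n_ms_responders,
            seed=int(np.random.default_rng([seed, p]).integers(2**31 - 1)),
        )
        for p in range(n_participants)
    ]
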