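"""Synthetic study generator: geometry, protocol balance, signal model."""
import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import periodogram

from nirsbci.features import TimeWindow, compute_slope
from nirsbci.synth import (
    OptodeGeometry,
    ParticipantProfile,
    build_protocol,
    default_geometry,
    enumerate_channels,
    simulate_study,
    simulate_trial,
)

from conftest import quiet_profile


class TestEnumerateChannels:
    def test_default_layout_yields_18_channels(self):
        channels = enumerate_channels(default_geometry())
        assert len(channels) == 18
        # 3 detectors x 3 source-pairs each x 2 wavelengths
        per_det = {d: sum(c.detector == d for c in channels) for d in ("D1", "D2", "D3")}
        assert per_det == {"D1": 6, "D2": 6, "D3": 6}
        assert {c.wavelength_nm for c in channels} == {690, 830}
        # each qualifying (detector, source-pair) appears at both wavelengths
        pairs = {(c.detector, c.source_pair) for c in channels}
        assert len(pairs) == 9 and len(channels) == 2 * len(pairs)

    def test_brute_force_distance_oracle(self):
        geom = default_geometry()
        expected = 0
        for dx, dy in geom.detectors.values():
            for sx, sy in geom.source_pairs.values():
                if abs(math.hypot(sx - dx, sy - dy) - 3.0) <= 0.01:
                    expected += 2
        assert len(enumerate_channels(geom)) == expected == 18

    def test_minimal_colocated_pair_gives_two_channels(self):
        geom = OptodeGeometry(detectors={"D1": (0.0, 0.0)}, source_pairs={"S1": (3.0, 0.0)})
        assert len(enumerate_channels(geom)) == 2

    def test_moved_source_pair_drops_to_16_at_zero_tolerance(self):
        geom = default_geometry()
        moved = dict(geom.source_pairs)
        # pull S5 from 3.0 to 2.5 cm from D3, along the line between them
        (dx, dy) = geom.detectors["D3"]
        (sx, sy) = moved["S5"]
        moved["S5"] = (dx + (sx - dx) * 2.5 / 3.0, dy + (sy - dy) * 2.5 / 3.0)
        channels = enumerate_channels(
            OptodeGeometry(detectors=geom.detectors, source_pairs=moved), tol_cm=0.0
        )
        assert len(channels) == 16

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enumerate_channels(OptodeGeometry(detectors={}, source_pairs={}))

    def test_no_qualifying_pair_names_the_separation_rule(self):
        geom = OptodeGeometry(detectors={"D1": (0.0, 0.0)}, source_pairs={"S1": (9.0, 0.0)})
        with pytest.raises(ValueError, match="3.0 cm"):
            enumerate_channels(geom)


class TestBuildProtocol:
    def test_default_counts(self, default_protocol):
        proto = default_protocol
        assert proto.n_trials == 96
        assert proto.n_segments == 288
        assert proto.label_counts() == {"MA": 72, "MS": 72, "NC": 144}

    def test_answer_patterns_balanced_within_session(self, default_protocol):
        for s in range(default_protocol.sessions):
            patterns = {}
            for t in range(default_protocol.trials_per_session):
                key = tuple(lab != "NC" for lab in default_protocol.labels[s, t])
                patterns[key] = patterns.get(key, 0) + 1
            assert len(patterns) == 8
            assert all(v == 4 for v in patterns.values())

    def test_ic_trials_split_evenly_between_tasks(self, default_protocol):
        tasks = []
        for s in range(default_protocol.sessions):
            for t in range(default_protocol.trials_per_session):
                labs = set(default_protocol.labels[s, t]) - {"NC"}
                assert len(labs) <= 1  # one task cue per trial
                if labs:
                    tasks.append(labs.pop())
        assert tasks.count("MA") == tasks.count("MS")

    def test_single_session_eight_trials(self):
        proto = build_protocol(sessions=1, trials_per_session=8, seed=5)
        assert proto.n_trials == 8
        assert proto.n_segments == 24
        counts = proto.label_counts()
        assert counts["NC"] == 12
        assert counts["MA"] == counts["MS"] == 6

    def test_seed_determinism(self):
        a = build_protocol(seed=7)
        b = build_protocol(seed=7)
        assert np.array_equal(a.labels, b.labels)
        c = build_protocol(seed=8)
        assert not np.array_equal(a.labels, c.labels)

    def test_unbalanceable_config_rejected(self):
        with pytest.raises(ValueError, match="divisible by 8"):
            build_protocol(trials_per_session=12)

    @given(
        sessions=st.integers(min_value=1, max_value=4),
        sets=st.integers(min_value=1, max_value=5),
        seed=st.integers(min_value=0, max_value=1000),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_label_count_conservation(self, sessions, sets, seed):
        proto = build_protocol(sessions=sessions, trials_per_session=8 * sets, seed=seed)
        counts = proto.label_counts()
        assert counts["MA"] == counts["MS"]
        assert counts["NC"] == counts["MA"] + counts["MS"]


class TestParticipantProfile:
    def test_nonresponder_must_have_zero_ms_effect(self):
        effect = {"MA": np.zeros(18), "MS": np.full(18, 0.1)}
        with pytest.raises(ValueError, match="non-responder"):
            ParticipantProfile(effect_slope=effect, ms_responder=False)

    @pytest.mark.parametrize(
        "field,value",
        [("noise_freq_resp", 0.5), ("noise_freq_cardiac", 0.5), ("noise_freq_mayer", 0.4)],
    )
    def test_noise_frequencies_must_stay_in_band(self, field, value):
        with pytest.raises(ValueError):
            ParticipantProfile(**{field: value})


class TestSimulateTrial:
    def test_null_profile_gives_constant_signal(self):
        rec = simulate_trial(quiet_profile(), ("NC", "NC", "NC"), seed=0)
        assert rec.data.shape == (18, 3000)
        assert np.ptp(rec.data) == 0.0

    def test_interval_boundaries_625_samples_each(self):
        rec = simulate_trial(quiet_profile(), ("MA", "NC", "MS"), seed=0)
        assert rec.interval_boundaries == [(375, 1000), (1375, 2000), (2375, 3000)]
        assert all(b - a == 625 for a, b in rec.interval_boundaries)

    def test_planted_slope_recovered_exactly(self):
        effect = {"MA": np.zeros(18), "MS": np.zeros(18)}
        effect["MA"][0] = 0.05
        prof = quiet_profile(effect_slope=effect, effect_onset_s=0.0)
        rec = simulate_trial(prof, ("MA", "NC", "NC"), seed=0)
        a, b = rec.interval_boundaries[0]
        slope = compute_slope(rec.data[0, a:b], TimeWindow(0, 20), rec.sample_rate_hz)
        assert slope == pytest.approx(0.05, abs=1e-12)
        # channels without a planted effect stay flat
        assert np.ptp(rec.data[1]) == 0.0
        # after the interval the response relaxes monotonically toward baseline
        tail = rec.data[0, 1000:1375] - prof.baseline
        assert np.all(np.diff(tail) <= 0)
        assert tail[-1] < 0.2 * tail[0]  # two time constants of decay over 12 s

    @pytest.mark.parametrize(
        "component,band",
        [
            ("noise_amp_mayer", (0.09, 0.11)),
            ("noise_amp_resp", (0.2, 0.3)),
            ("noise_amp_cardiac", (0.8, 1.2)),
        ],
    )
    def test_noise_component_peaks_in_its_band(self, component, band):
        prof = quiet_profile(**{component: 1.0})
        rec = simulate_trial(prof, ("NC", "NC", "NC"), seed=3)
        x = rec.data[0] - rec.data[0].mean()
        f, pxx = periodogram(x, fs=rec.sample_rate_hz)
        peak = f[pxx.argmax()]
        assert band[0] - 0.03 <= peak <= band[1] + 0.03

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            simulate_trial(quiet_profile(), ("XX", "NC", "NC"), seed=0)
        with pytest.raises(ValueError, match="positive"):
            simulate_trial(quiet_profile(), ("NC",) * 3, seed=0, vigilant_duration_s=-1.0)


class TestSimulateStudy:
    def test_default_counts_one_participant(self, default_protocol):
        prof = quiet_profile(white_noise_sd=0.1)
        recordings, table = simulate_study([prof], default_protocol, seed=9)
        assert len(recordings) == 96
        assert len(table) == 288
        assert table["class"].value_counts().to_dict() == {"NC": 144, "MA": 72, "MS": 72}

    def test_multiplicative_in_participants(self):
        proto = build_protocol(sessions=1, trials_per_session=8, seed=0)
        profs = [quiet_profile(white_noise_sd=0.1) for _ in range(3)]
        for i, p in enumerate(profs):
            p.participant_id = i
        recordings, table = simulate_study(profs, proto, seed=1)
        assert len(recordings) == 3 * 8
        assert sorted(table["participant"].unique()) == [0, 1, 2]

    def test_seed_determinism_byte_identical_table_and_data(self, default_protocol):
        prof = ParticipantProfile()
        rec_a, tab_a = simulate_study([prof], default_protocol, seed=17)
        rec_b, tab_b = simulate_study([prof], default_protocol, seed=17)
        assert tab_a.to_csv(index=False) == tab_b.to_csv(index=False)
        assert all(np.array_equal(a.data, b.data) for a, b in zip(rec_a, rec_b))
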