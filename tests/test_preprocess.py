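"""Preprocessing: per-trial standardization, detrending, filter design, segmentation."""
import dataclasses

import numpy as np
import pytest

from nirsbci.preprocess import (
    FilterSpec,
    design_lowpass,
    detrend_trial,
    extract_segments,
    filter_response_db,
    filter_segment,
    normalize_trial,
    preprocess_trial,
)
from nirsbci.synth import ParticipantProfile, simulate_trial

from conftest import quiet_profile


def _ols_slope_intercept(y, fs=31.25):
    t = np.arange(len(y)) / fs
    return np.polyfit(t, y, 1)


class TestNormalize:
    def test_zero_mean_unit_sd_per_channel(self, noisy_recording):
        out = normalize_trial(noisy_recording)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.data.std(axis=1), 1.0, rtol=1e-10)

    def test_ordering_preserved(self, noisy_recording):
        rec = dataclasses.replace(
            noisy_recording,
            data=np.tile(np.array([1.0, 2.0, 3.0]), (18, 1)),
        )
        out = normalize_trial(rec)
        assert np.all(np.diff(out.data[0]) > 0)

    def test_idempotent(self, noisy_recording):
        once = normalize_trial(noisy_recording)
        twice = normalize_trial(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)

    def test_dead_channel_named_in_error(self, noisy_recording):
        data = noisy_recording.data.copy()
        data[4] = 5.0
        rec = dataclasses.replace(noisy_recording, data=data)
        name = noisy_recording.channel_names[4]
        with pytest.raises(ValueError, match=name):
            normalize_trial(rec)


class TestDetrend:
    def test_pure_ramp_removed_exactly(self, noisy_recording):
        t = noisy_recording.times
        rec = dataclasses.replace(
            noisy_recording, data=np.outer(np.arange(1, 19), t) + 7.0
        )
        out = detrend_trial(rec)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-8)

    def test_whole_period_sinusoid_nearly_unchanged(self, noisy_recording):
        t = noisy_recording.times
        sig = np.sin(2 * np.pi * 0.5 * t)  # 48 whole periods over 96 s
        rec = dataclasses.replace(noisy_recording, data=np.tile(sig, (18, 1)))
        out = detrend_trial(rec)
        slope, intercept = _ols_slope_intercept(out.data[0])
        assert abs(slope) < 1e-6
        assert np.max(np.abs(out.data[0] - sig)) < 0.05

    def test_output_regression_slope_and_intercept_zero(self, noisy_recording):
        out = detrend_trial(noisy_recording)
        for ch in range(0, 18, 6):
            slope, intercept = _ols_slope_intercept(out.data[ch])
            assert slope == pytest.approx(0.0, abs=1e-8)
            assert intercept == pytest.approx(0.0, abs=1e-8)


class TestDesignLowpass:
    def test_stopband_attenuation_at_least_50_db(self):
        sos = design_lowpass(FilterSpec())
        f = np.linspace(0.5, 31.25 / 2, 4096)
        atten = -filter_response_db(sos, f)
        assert atten.min() >= 50.0 - 1e-6

    def test_passband_loss_at_most_6_db(self):
        sos = design_lowpass(FilterSpec())
        f = np.linspace(1e-4, 0.1, 512)
        loss = -filter_response_db(sos, f)
        assert loss.max() <= 6.0

    def test_unit_dc_gain(self):
        sos = design_lowpass(FilterSpec())
        assert filter_response_db(sos, [0.0])[0] == pytest.approx(0.0, abs=1e-9)

    def test_unachievable_spec_names_failing_constraint(self):
        # stop edge so close to the cut-off that a 3rd-order design cannot
        # reach 50 dB there while keeping the passband within 6 dB
        with pytest.raises(ValueError, match="passband"):
            design_lowpass(FilterSpec(stop_hz=0.11))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(cutoff_hz=0.5, stop_hz=0.1).validate()


class TestExtractSegments:
    def test_three_segments_of_625_samples(self, noisy_recording):
        segs = extract_segments(noisy_recording, ("MA", "NC", "MS"))
        assert len(segs) == 3
        assert all(s.data.shape == (18, 625) for s in segs)

    def test_labels_passed_through_in_order(self, noisy_recording):
        segs = extract_segments(noisy_recording, ("MA", "NC", "MS"))
        assert [s.label for s in segs] == ["MA", "NC", "MS"]
        assert [s.interval_index for s in segs] == [0, 1, 2]

    def test_truncated_recording_rejected(self, noisy_recording):
        rec = dataclasses.replace(noisy_recording, data=noisy_recording.data[:, :2000])
        with pytest.raises(ValueError, match="outside"):
            extract_segments(rec, ("MA", "NC", "MS"))


@pytest.fixture(scope="module")
def sos():
    return design_lowpass(FilterSpec())


class TestFilterSegment:
    def _segment(self, recording, data):
        seg = extract_segments(recording, ("NC", "NC", "NC"))[0]
        seg.data = data
        return seg

    def test_dc_input_unchanged(self, noisy_recording, sos):
        seg = self._segment(noisy_recording, np.full((18, 625), 3.5))
        out = filter_segment(seg, sos)
        np.testing.assert_allclose(out.data, 3.5, rtol=1e-9)
        assert out.data.shape == seg.data.shape

    def test_1hz_sinusoid_attenuated_50_db_steady_state(self, sos):
        # steady-state attenuation, free of finite-segment edge effects:
        # filter a long sinusoid and measure the central third
        from scipy.signal import sosfiltfilt

        t = np.arange(6000) / 31.25
        x = np.sin(2 * np.pi * 1.0 * t)
        out = sosfiltfilt(sos, x, padlen=5998)
        in_rms = 1.0 / np.sqrt(2)  # closed form for a unit sinusoid
        mid_rms = np.sqrt(np.mean(out[2000:4000] ** 2))
        assert 20 * np.log10(mid_rms / in_rms) <= -50.0

    def test_1hz_sinusoid_strongly_reduced_on_20s_segment(self, noisy_recording, sos):
        # on a finite 20 s segment the truncated sinusoid leaks low-frequency
        # energy into the passband, so attenuation is bounded by leakage, not
        # by the filter's 50 dB stop-band figure
        t = np.arange(625) / 31.25
        x = np.sin(2 * np.pi * 1.0 * t)
        seg = self._segment(noisy_recording, np.tile(x, (18, 1)))
        out = filter_segment(seg, sos)
        in_rms = 1.0 / np.sqrt(2)
        ratio_db = 20 * np.log10(np.sqrt(np.mean(out.data[0] ** 2)) / in_rms)
        assert ratio_db <= -20.0

    def test_slow_sinusoid_slope_preserved(self, noisy_recording, sos):
        t = np.arange(625) / 31.25
        x = np.sin(2 * np.pi * 0.02 * t)
        seg = self._segment(noisy_recording, np.tile(x, (18, 1)))
        out = filter_segment(seg, sos)
        slope_in, _ = _ols_slope_intercept(x)
        slope_out, _ = _ols_slope_intercept(out.data[0])
        assert slope_out == pytest.approx(slope_in, rel=0.05)

    def test_linearity(self, noisy_recording, sos, rng):
        x = rng.normal(size=(18, 625))
        y = rng.normal(size=(18, 625))
        seg_x = self._segment(noisy_recording, x)
        seg_y = self._segment(noisy_recording, y)
        seg_mix = self._segment(noisy_recording, 2.0 * x + 3.0 * y)
        mix_out = filter_segment(seg_mix, sos).data
        combo = 2.0 * filter_segment(seg_x, sos).data + 3.0 * filter_segment(seg_y, sos).data
        np.testing.assert_allclose(mix_out, combo, atol=1e-9)


class TestPipelineOrder:
    def test_counts_channels_labels_invariant(self):
        prof = ParticipantProfile()
        rec = simulate_trial(prof, ("MS", "MA", "NC"), seed=11)
        from nirsbci.preprocess import design_lowpass

        segs = preprocess_trial(rec, ("MS", "MA", "NC"), design_lowpass(FilterSpec()))
        assert [s.label for s in segs] == ["MS", "MA", "NC"]
        assert all(s.data.shape == (18, 625) for s in segs)
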