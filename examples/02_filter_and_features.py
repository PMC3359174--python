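"""Design the preprocessing filter and extract slope features.

Shows the Chebyshev II low-pass meeting its published constraints, then
runs one trial through normalize -> detrend -> segment -> filter and
builds the 180-column slope feature block for its three segments.
"""
import numpy as np

from nirsbci import (
    FilterSpec,
    build_feature_matrix,
    default_profile,
    design_lowpass,
    enumerate_windows,
    preprocess_trial,
    simulate_trial,
)
from nirsbci.preprocess import filter_response_db

spec = FilterSpec()
sos = design_lowpass(spec)
stop = np.linspace(spec.stop_hz, spec.sample_rate_hz / 2, 2048)
print("min stop-band attenuation: %.1f dB (design requires >= %.0f)"
      % ((-filter_response_db(sos, stop)).min(), spec.min_stopband_atten_db))
pb = np.linspace(1e-3, spec.cutoff_hz, 256)
print("max pass-band loss: %.2f dB (design allows <= %.0f)"
      % ((-filter_response_db(sos, pb)).max(), spec.max_passband_loss_db))

profile = default_profile(seed=1)
labels = ("MA", "NC", "MS")
rec = simulate_trial(profile, labels, seed=1)
segments = preprocess_trial(rec, labels, sos)
print("segments:", [(s.label, s.data.shape) for s in segments])

fm = build_feature_matrix(segments, rec.sample_rate_hz)
print("feature matrix:", fm.values.shape, "= 3 segments x (18 channels x"
      f" {len(enumerate_windows())} windows)")
print("slope range (normalized units/s): %.3f .. %.3f"
      % (fm.values.min(), fm.values.max()))
# Each value is the least-squares slope of one channel over one of the ten
# windows inside the 20 s vigilant period — the classifier's raw material.
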