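"""Turn a synthetic manatee call into the classifier's 513 x 75 input."""

import numpy as np

from sirenet import features, soundscape_sim as sim

rng = np.random.default_rng(0)

# One tonal call: 3 kHz fundamental, 3 harmonics, 0.5 s.
params = sim.CallParams(
    f0_hz=(3000.0, 3000.0), duration_s=(0.5, 0.5), chirp_slope_hz_per_s=(200.0, 200.0)
)
call = sim.synth_call(params, rate_hz=96_000, rng=rng)
noise = 0.05 * rng.standard_normal(len(call))
audio = 0.3 * call + noise

slices = features.slice_audio(audio, recording_id="demo")
print(f"{len(call)} samples -> {len(slices)} slices of 19,200 samples each")

spec = features.spectrogram(slices[1])  # a slice from the middle of the call
print(f"spectrogram shape: {spec.values.shape} (freq bins x time frames)")
print(f"resolution: {spec.freq_resolution_hz:.2f} Hz x {spec.time_resolution_s*1e3:.2f} ms")

peak_bins = np.argmax(spec.values, axis=0)
peak_hz = np.median(peak_bins) * spec.freq_resolution_hz
print(f"median per-frame peak frequency: {peak_hz:.0f} Hz (fundamental at ~3 kHz)")
# Values are peak-normalized dB in [0, 1]: the brightest pixel of every
# (non-constant) slice is exactly 1 and the darkest exactly 0.
print(f"value range: [{spec.values.min():.1f}, {spec.values.max():.1f}]")
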