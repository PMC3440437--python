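"""Noise-multiple spike detection on a synthetic raw waveform.

Injects known spike times into Gaussian background noise, estimates the
per-channel noise scale robustly, and detects threshold crossings at four
times the noise level.
"""

import numpy as np

from countdec import (
    DetectionParams,
    SpikeTrainSet,
    default_spike_shape,
    detect_spikes,
    estimate_noise,
    synth_waveform,
)

fs = 30_000.0
rng = np.random.default_rng(0)
true_times = np.sort(rng.uniform(0.05, 4.95, 60))
true_times = true_times[np.concatenate(([True], np.diff(true_times) > 2e-3))]
spikes = SpikeTrainSet([true_times], duration=5.0)

shape = default_spike_shape(fs, amplitude=10.0)  # 10x the noise scale
waveform = synth_waveform(spikes, fs, noise_scale=1.0, spike_shape=shape, seed=1)

sigma = estimate_noise(waveform, channel=1)
out = detect_spikes(waveform, DetectionParams(multiple=4.0, polarity="negative"))

hits = sum(np.min(np.abs(out.spikes[0] - t)) < 1e-3 for t in true_times)
print(f"estimated noise scale : {sigma:.3f} (true 1.0)")
print(f"injected / detected   : {true_times.size} / {out.spikes[0].size}")
print(f"within 1 ms of truth  : {hits}")

# The median-absolute-deviation estimate stays near the true noise scale
# despite the spikes, and a threshold at 4 sigma recovers essentially every
# injected event with few or no false positives.
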