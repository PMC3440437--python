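"""Single-threshold spike detection on band-passed extracellular waveforms.

Each channel is compared against a programmable amplitude threshold; one event
is emitted per threshold crossing, with a dead time suppressing re-triggers.
Thresholds can be set per channel in absolute units or automatically as a
multiple of a robust per-channel noise estimate, the standard approach for
high-channel-count arrays where manual tuning is impractical.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .core import SpikeTrainSet

#: Fewest samples accepted by the noise estimator.
MIN_NOISE_SAMPLES = 100

#: MAD -> Gaussian-equivalent standard deviation.
_MAD_SCALE = 1.4826022185056018


@dataclass
class WaveformRecord:
    """An S x N sampled multichannel waveform."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim == 1:
            s = s[:, None]
        if s.ndim != 2:
            raise ValueError("samples must be an S x N matrix")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = s

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class DetectionParams:
    """Detection configuration.

    ``mode="absolute"`` uses ``threshold`` (scalar or per-channel array) in
    amplitude units; ``mode="noise-multiple"`` sets each channel's threshold
    to ``multiple`` times its robust noise scale.  ``polarity`` selects which
    excursions count as spikes; extracellular somatic spikes are dominantly
    negative-going, hence the default.
    """

    mode: str = "noise-multiple"
    threshold: float | np.ndarray | None = None
    multiple: float = 4.0
    polarity: str = "negative"
    dead_time: float = 1e-3

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "noise-multiple"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "absolute" and self.threshold is None:
            raise ValueError("absolute mode requires a threshold")
        if self.mode == "noise-multiple" and self.multiple <= 0:
            raise ValueError("multiple must be positive")
        if self.polarity not in ("positive", "negative", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.dead_time < 0:
            raise ValueError("dead_time must be non-negative")


def estimate_noise(waveform: WaveformRecord, channel: int) -> float:
    """Robust noise scale of one channel (1-based index).

    Median absolute deviation scaled to the Gaussian-equivalent standard
    deviation; sparse large spikes barely move the estimate, unlike the raw
    standard deviation.
    """
    if not 1 <= channel <= waveform.n_channels:
        raise ValueError(f"channel {channel} outside 1..{waveform.n_channels}")
    x = waveform.samples[:, channel - 1]
    if x.size < MIN_NOISE_SAMPLES:
        raise ValueError(
            f"need at least {MIN_NOISE_SAMPLES} samples to estimate noise, "
            f"got {x.size}"
        )
    return float(_MAD_SCALE * np.median(np.abs(x - np.median(x))))


def _crossings(x: np.ndarray, thr: float) -> np.ndarray:
    """Sample indices where x crosses thr from below."""
    above = x >= thr
    idx = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        idx = np.concatenate(([0], idx))
    return idx


def detect_spikes(waveform: WaveformRecord, params: DetectionParams) -> SpikeTrainSet:
    """Detect threshold-crossing events on every channel.

    One event is emitted per upward crossing of the effective threshold (the
    rectified signal for ``polarity="both"``); events closer than
    ``dead_time`` to the previous accepted event on the same channel are
    suppressed.  Event times are the crossing-sample times.
    """
    fs = waveform.sampling_rate
    dead_samples = int(np.ceil(params.dead_time * fs))
    trains = []
    for ch in range(waveform.n_channels):
        x = waveform.samples[:, ch]
        if params.polarity == "negative":
            eff = -x
        elif params.polarity == "both":
            eff = np.abs(x)
        else:
            eff = x
        if params.mode == "absolute":
            thr = np.atleast_1d(np.asarray(params.threshold, dtype=float))
            t = float(thr[ch]) if thr.size > 1 else float(thr[0])
        else:
            t = params.multiple * estimate_noise(waveform, ch + 1)
        idx = _crossings(eff, t)
        if dead_samples > 0 and idx.size > 1:
            kept = [idx[0]]
            for i in idx[1:]:
                if i - kept[-1] >= dead_samples:
                    kept.append(i)
            idx = np.array(kept)
        trains.append(idx / fs)
    return SpikeTrainSet(trains, duration=waveform.duration)


# ------------------------------------------------------------------ waveform IO


def write_waveform(waveform: WaveformRecord, path) -> None:
    """CSV (``.csv``) or HDF5 (anything else) with sampling-rate metadata."""
    path = str(path)
    if path.endswith(".csv"):
        header = f"# sampling_rate_hz={waveform.sampling_rate!r}\n" + ",".join(
            f"ch{i + 1}" for i in range(waveform.n_channels)
        )
        np.savetxt(path, waveform.samples, delimiter=",", header=header, comments="")
    else:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("samples", data=waveform.samples)
            d.attrs["sampling_rate_hz"] = waveform.sampling_rate


def read_waveform(path) -> WaveformRecord:
    path = str(path)
    if path.endswith(".csv"):
        fs = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "sampling_rate_hz=" in first:
            fs = float(first.split("=", 1)[1])
        if fs is None:
            raise ValueError(f"{path}: missing '# sampling_rate_hz=' metadata")
        samples = np.loadtxt(path, delimiter=",", skiprows=2, ndmin=2)
        return WaveformRecord(samples, fs)
    with h5py.File(path, "r") as f:
        d = f["samples"]
        return WaveformRecord(d[...], float(d.attrs["sampling_rate_hz"]))
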