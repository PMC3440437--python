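"""Synthetic place-cell recordings on a 1-D track.

The generator emulates the data regime the decoder is built for: a population
of hippocampal place cells with unimodal, approximately Gaussian receptive
fields tiling a linear track, firing Poisson-like spikes while the subject
traverses the track back and forth.  It also produces the two auxiliary
fixtures the evaluation needs: rate-matched random-time noise channels (for
leave-one-out robustness) and raw synthetic waveforms with known spike times
(for exercising the detection stage).

Default scenario
----------------
32 cells tiling 32 track states on a 3.5 m track, 250 ms counting windows,
3-bit counters — mirroring the demonstrated 32-channel / 32-state system.
The behavioral defaults (mean traversal speed 0.1 m/s with 10% jitter,
8 traversals) give a few minutes of session time with several labeled windows
per state per traversal; field SD 0.10 m, peak rate 20 Hz and baseline 0.2 Hz
are typical of place fields on a linear track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SpikeTrainSet
from .detect import WaveformRecord


@dataclass
class PlaceCellParams:
    """Gaussian spatial tuning: rate(x) = baseline + (peak − baseline) ·
    exp(−(x − center)² / (2 · width²))."""

    center: float
    width: float
    peak_rate: float
    baseline_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.baseline_rate < 0 or self.peak_rate < self.baseline_rate:
            raise ValueError("rates must satisfy 0 <= baseline <= peak")

    def rate(self, position: np.ndarray) -> np.ndarray:
        x = np.asarray(position, dtype=float)
        return self.baseline_rate + (self.peak_rate - self.baseline_rate) * np.exp(
            -((x - self.center) ** 2) / (2.0 * self.width**2)
        )


@dataclass
class TrackConfig:
    """Linear-track behavior: alternate end-to-end traversals at jittered
    speed."""

    length: float = 3.5
    K: int = 32
    mean_speed: float = 0.1
    traversals: int = 8
    speed_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.length <= 0 or self.K < 1:
            raise ValueError("length must be positive and K >= 1")
        if self.mean_speed <= 0 or self.traversals < 1:
            raise ValueError("mean_speed must be positive and traversals >= 1")
        if not 0 <= self.speed_jitter < 1:
            raise ValueError("speed_jitter must lie in [0, 1)")

    @property
    def segment_length(self) -> float:
        return self.length / self.K


@dataclass
class Trajectory:
    """Sampled (time, position) pairs plus the per-traversal end times."""

    times: np.ndarray
    positions: np.ndarray
    sweep_end_times: np.ndarray

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def as_pairs(self) -> np.ndarray:
        return np.column_stack([self.times, self.positions])

    def position_at(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.positions)


def simulate_trajectory(
    track: TrackConfig, seed: int, dt: float = 0.01
) -> Trajectory:
    """Back-and-forth sweeps of the track at per-traversal jittered speed,
    sampled on a fixed dt grid."""
    rng = np.random.default_rng(seed)
    speeds = track.mean_speed * (
        1.0 + track.speed_jitter * rng.uniform(-1.0, 1.0, size=track.traversals)
    )
    durations = track.length / speeds
    knots_t = np.concatenate([[0.0], np.cumsum(durations)])
    knots_x = np.array(
        [0.0] + [track.length if s % 2 == 0 else 0.0 for s in range(track.traversals)]
    )
    times = np.arange(0.0, knots_t[-1] + dt / 2, dt)
    times = times[times <= knots_t[-1]]
    positions = np.interp(times, knots_t, knots_x)
    return Trajectory(times, positions, knots_t[1:])


def simulate_spikes(
    trajectory: Trajectory, cells: list[PlaceCellParams], seed: int
) -> SpikeTrainSet:
    """Inhomogeneous Poisson spiking by thinning, one channel per cell."""
    if not cells:
        raise ValueError("at least one cell is required")
    rng = np.random.default_rng(seed)
    duration = trajectory.duration
    trains = []
    for cell in cells:
        lam_max = cell.peak_rate
        if lam_max == 0:
            trains.append(np.array([]))
            continue
        n = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n))
        rate = cell.rate(trajectory.position_at(cand))
        keep = rng.uniform(0.0, lam_max, size=n) < rate
        trains.append(cand[keep])
    return SpikeTrainSet(trains, duration)


def tiled_place_cells(
    track: TrackConfig,
    width: float = 0.10,
    peak_rate: float = 20.0,
    baseline_rate: float = 0.2,
    n_cells: int | None = None,
) -> list[PlaceCellParams]:
    """One cell per track state by default, centered on the segment centers,
    so the population's receptive fields tile the track."""
    n = track.K if n_cells is None else n_cells
    centers = (np.arange(n) + 0.5) * track.length / n
    return [PlaceCellParams(c, width, peak_rate, baseline_rate) for c in centers]


def make_noise_channel(
    spikes: np.ndarray, duration: float, seed: int
) -> np.ndarray:
    """Rate-matched noise: the same number of events, at i.i.d. uniform random
    times on [0, duration], sorted."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    return np.sort(rng.uniform(0.0, duration, size=np.asarray(spikes).size))


def default_spike_shape(
    sampling_rate: float, amplitude: float = 10.0, duration: float = 1.2e-3
) -> np.ndarray:
    """A simple biphasic extracellular spike: sharp negative lobe followed by
    a shallow positive rebound."""
    n = max(int(round(duration * sampling_rate)), 4)
    t = np.arange(n) / n
    trough = 0.15  # fractional time of the negative peak
    neg = -amplitude * (t / trough) * np.exp(1.0 - t / trough)
    rebound = 0.2 * amplitude * np.sin(np.pi * t) * t
    return neg + rebound


def synth_waveform(
    spikes: SpikeTrainSet,
    sampling_rate: float,
    noise_scale: float,
    spike_shape: np.ndarray,
    seed: int,
) -> WaveformRecord:
    """Gaussian background noise with the spike shape superposed at each event
    time; ground-truth times stay in ``spikes`` for oracle checks."""
    shape = np.asarray(spike_shape, dtype=float)
    if not np.all(np.isfinite(shape)):
        raise ValueError("spike_shape must be finite")
    rng = np.random.default_rng(seed)
    S = int(np.ceil(spikes.duration * sampling_rate))
    samples = rng.normal(0.0, noise_scale, size=(S, spikes.channel_count))
    L = shape.size
    overlapped = False
    for ch, times in enumerate(spikes.spikes):
        idx = np.round(times * sampling_rate).astype(int)
        if idx.size > 1 and np.any(np.diff(idx) < L):
            overlapped = True
        for i in idx:
            stop = min(i + L, S)
            if stop > i:
                samples[i:stop, ch] += shape[: stop - i]
    if overlapped:
        warnings.warn("overlapping spike injections; shapes superposed")
    return WaveformRecord(samples, sampling_rate)
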