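"""Domain types shared by every stage of the decoder.

The decoder operates on windowed, saturating spike counts: each input channel
is monitored over successive windows of length ``W`` seconds and the number of
detected spikes is registered in a ``b``-bit counter that saturates at
``2**b - 1`` (it never wraps).  Channel and state indices are 1-based
throughout the public API, matching the printed rule-table convention; NumPy
array axes are the only 0-based objects, and conversion happens exactly where
arrays are indexed.

The ``UNKNOWN_STATE`` sentinel (0) marks windows of a training trajectory with
no position sample; such windows are excluded from histogram accumulation and
from performance metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: State-sequence sentinel for windows with no label.
UNKNOWN_STATE = 0

#: The one rule operation implemented by the internal unit: the logical AND of
#: "count >= threshold" over every (channel, threshold) entry of a template.
OP_CONJUNCTION = "conjunction_at_least"


def counter_max(counter_bits: int) -> int:
    """Saturation value of a ``counter_bits``-bit spike counter."""
    if counter_bits < 1:
        raise ValueError(f"counter_bits must be >= 1, got {counter_bits}")
    return (1 << counter_bits) - 1


@dataclass
class SpikeTrainSet:
    """Per-channel spike event times, in seconds, over a fixed recording span.

    Parameters
    ----------
    spikes
        One array of non-decreasing event times per channel.
    duration
        Length of the recording in seconds.  Events must lie in
        ``[0, duration]``.
    """

    spikes: list[np.ndarray]
    duration: float

    def __post_init__(self) -> None:
        if len(self.spikes) < 1:
            raise ValueError("at least one channel is required")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        clean = []
        for i, times in enumerate(self.spikes):
            t = np.asarray(times, dtype=float)
            if t.ndim != 1:
                raise ValueError(f"channel {i + 1}: spike times must be 1-D")
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError(
                    f"channel {i + 1}: spike times outside [0, {self.duration}]"
                )
            if t.size and np.any(np.diff(t) < 0):
                raise ValueError(f"channel {i + 1}: spike times must be sorted")
            clean.append(t)
        self.spikes = clean

    @property
    def channel_count(self) -> int:
        return len(self.spikes)

    def total_counts(self) -> np.ndarray:
        """Total number of events per channel."""
        return np.array([t.size for t in self.spikes], dtype=int)


@dataclass
class CountMatrix:
    """Windowed, saturating spike counts: one row per window, one column per
    channel.  This matrix is the only input the internal decoding unit sees."""

    counts: np.ndarray
    window_length: float
    counter_bits: int
    start_time: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2:
            raise ValueError("counts must be a T x N matrix")
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        cmax = counter_max(self.counter_bits)
        if c.size and (c.min() < 0 or c.max() > cmax):
            raise ValueError(
                f"counts must lie in [0, {cmax}] for a "
                f"{self.counter_bits}-bit counter"
            )
        self.counts = c

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]


@dataclass
class StateSequence:
    """Per-window state labels in ``1..K`` with 0 as the unknown sentinel."""

    states: np.ndarray
    K: int
    segment_length: float | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=int)
        if s.ndim != 1:
            raise ValueError("states must be 1-D")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if s.size and (s.min() < 0 or s.max() > self.K):
            raise ValueError(f"states must lie in 0..{self.K} (0 = unknown)")
        self.states = s

    @property
    def n_windows(self) -> int:
        return self.states.size

    def known(self) -> np.ndarray:
        """Boolean mask of labeled windows."""
        return self.states != UNKNOWN_STATE

    def positions(self) -> np.ndarray:
        """Segment-center positions (meters) for labeled windows; NaN where
        unknown.  Requires ``segment_length``."""
        if self.segment_length is None:
            raise ValueError("segment_length is not set")
        pos = (self.states - 0.5) * self.segment_length
        return np.where(self.known(), pos, np.nan)


@dataclass
class Template:
    """One decoding rule: the template for ``state`` fires in a window when
    every listed channel's spike count attains its threshold."""

    state: int
    entries: list[tuple[int, int]] = field(default_factory=list)
    op: str = OP_CONJUNCTION


@dataclass
class TemplateSet:
    """The decoder's program tape: per-state threshold rules.

    Each template holds at most ``M`` (channel, threshold) pairs; a state may
    own several templates (combined by OR during decoding) and templates may
    be empty, in which case the state's output bit is constantly 0 and is left
    for the external smoother to resolve.
    """

    K: int
    M: int
    counter_bits: int
    templates: list[Template] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.K < 1 or self.M < 0:
            raise ValueError("K must be >= 1 and M >= 0")
        cmax = counter_max(self.counter_bits)
        for tpl in self.templates:
            if not 1 <= tpl.state <= self.K:
                raise ValueError(f"template state {tpl.state} outside 1..{self.K}")
            if len(tpl.entries) > self.M:
                raise ValueError(
                    f"template for state {tpl.state} has more than M={self.M} entries"
                )
            for ch, theta in tpl.entries:
                if ch < 1:
                    raise ValueError(f"channel index {ch} must be >= 1")
                if not 1 <= theta <= cmax:
                    raise ValueError(
                        f"threshold {theta} outside 1..{cmax} "
                        f"for a {self.counter_bits}-bit counter"
                    )

    def for_state(self, state: int) -> list[Template]:
        return [t for t in self.templates if t.state == state]

    def max_channel(self) -> int:
        chans = [ch for t in self.templates for ch, _ in t.entries]
        return max(chans, default=0)


@dataclass
class DecoderOutput:
    """The internal unit's compressed output stream: a T x K binary score
    matrix, one bit per state per window."""

    bits: np.ndarray
    window_length: float

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=np.uint8)
        if b.ndim != 2:
            raise ValueError("bits must be a T x K matrix")
        if b.size and b.max() > 1:
            raise ValueError("bits must be 0 or 1")
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        self.bits = b

    @property
    def n_windows(self) -> int:
        return self.bits.shape[0]

    @property
    def K(self) -> int:
        return self.bits.shape[1]


def window_counts(
    spikes: SpikeTrainSet, window_length: float, counter_bits: int
) -> CountMatrix:
    """Count spikes per channel in consecutive half-open windows.

    Window ``t`` covers ``[t*W, (t+1)*W)``: a spike exactly on a boundary
    belongs to the later window, matching synchronous counter-reset semantics.
    Counts saturate at ``2**counter_bits - 1``.  A trailing partial window is
    dropped (``T = floor(duration / W)``).
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    cmax = counter_max(counter_bits)
    T = int(np.floor(spikes.duration / window_length))
    if T == 0:
        raise ValueError("no data: recording shorter than one window")
    counts = np.zeros((T, spikes.channel_count), dtype=int)
    for i, times in enumerate(spikes.spikes):
        idx = np.floor(times / window_length).astype(int)
        idx = idx[idx < T]  # events past the last full window are dropped
        np.add.at(counts[:, i], idx, 1)
    np.minimum(counts, cmax, out=counts)
    return CountMatrix(counts, window_length, counter_bits)


def discretize_trajectory(
    positions: Sequence[tuple[float, float]] | np.ndarray,
    track_length: float,
    K: int,
    window_length: float,
    duration: float | None = None,
) -> StateSequence:
    """Bin a sampled (time, position) trajectory into per-window track states.

    The state of window ``t`` is ``1 + floor(K * mean_pos / L)``, clamped to
    ``K`` at the right edge, where ``mean_pos`` is the mean of the position
    samples falling in the window.  Windows with no sample get the unknown
    sentinel.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if track_length <= 0:
        raise ValueError("track_length must be positive")
    arr = np.asarray(positions, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("positions must be a sequence of (time, position) pairs")
    t, p = arr[:, 0], arr[:, 1]
    if p.size and (p.min() < 0 or p.max() > track_length):
        raise ValueError("positions outside [0, track_length]")
    if duration is None:
        duration = float(t.max()) if t.size else 0.0
    T = int(np.floor(duration / window_length))
    if T == 0:
        raise ValueError("no data: trajectory shorter than one window")
    win = np.floor(t / window_length).astype(int)
    keep = win < T
    sums = np.zeros(T)
    nums = np.zeros(T, dtype=int)
    np.add.at(sums, win[keep], p[keep])
    np.add.at(nums, win[keep], 1)
    states = np.full(T, UNKNOWN_STATE, dtype=int)
    sampled = nums > 0
    mean_pos = sums[sampled] / nums[sampled]
    states[sampled] = np.minimum(
        1 + np.floor(K * mean_pos / track_length).astype(int), K
    )
    return StateSequence(states, K, segment_length=track_length / K)
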