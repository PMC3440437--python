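"""Evaluation and resource models.

Per-state binary-classification metrics and trajectory correlation quantify
decoding quality; the compression-factor and operation-count models quantify
what the internal unit saves.  Sensitivity and specificity are properties of
the decoding function alone; positive predictive value additionally depends
on state prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DecoderOutput, SpikeTrainSet, StateSequence

# Per-frame operation accounting for the internal unit.  One computational
# frame = one pass through all templates for one spike-count vector.  Each of
# the K_T x M threshold comparisons costs one memory access (threshold +
# channel pointer fetch), one multiplexer selection of the addressed counter,
# one comparison, b_logic binary-logic operations combining the comparison
# into the template's result, and one shift-register update; per frame there
# is additionally one clock-counter operation and K output-shift-register
# updates assembling the outgoing score vector.
PER_COMPARISON_CATEGORIES = (
    "memory_access",
    "multiplexer",
    "comparison",
    "shift_register_template",
)


@dataclass
class OpCountModel:
    """Operations per computational frame, by category, for the internal
    decoder, plus the frame rate (1/W) at which frames are evaluated."""

    tallies: dict[str, float]
    frame_rate: float
    K_T: int
    M: int
    b_logic: int = 1

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.tallies.values()):
            raise ValueError("operation tallies must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @classmethod
    def for_configuration(
        cls, K_T: int, M: int, K: int, b_logic: int = 1, frame_rate: float = 10.0
    ) -> "OpCountModel":
        """Build the per-frame tallies for K_T templates of M thresholds each
        decoding K states."""
        n_cmp = K_T * M
        tallies = {cat: float(n_cmp) for cat in PER_COMPARISON_CATEGORIES}
        tallies["binary_logic"] = float(n_cmp * b_logic)
        tallies["clock_counter"] = 1.0
        tallies["shift_register_output"] = float(K)
        return cls(tallies, frame_rate, K_T, M, b_logic)

    @property
    def ops_per_frame(self) -> float:
        return float(sum(self.tallies.values()))


def op_count(model: OpCountModel) -> float:
    """Total operations per second: frame rate times the per-frame total."""
    return model.frame_rate * model.ops_per_frame


@dataclass
class CompressionInputs:
    """Raw-acquisition side (N channels, B bits at f_s Hz) versus decoder
    output side (K bits per W-second window)."""

    N: int
    B: int
    f_s: float
    K: int
    W: float

    def __post_init__(self) -> None:
        if min(self.N, self.B, self.f_s, self.K, self.W) <= 0:
            raise ValueError("all compression inputs must be positive")


def compression_factor(inputs: CompressionInputs) -> float:
    """Raw input bit rate divided by decoder output bit rate:
    (N · B · f_s) / (K / W)."""
    return inputs.N * inputs.B * inputs.f_s * inputs.W / inputs.K


def classification_metrics(
    output: DecoderOutput, labels: StateSequence
) -> pd.DataFrame:
    """Per-state sensitivity, specificity and PPV of the raw decoder bits.

    Windows with the unknown label are excluded.  A state never labeled has
    undefined sensitivity, and a state whose bit never fires has undefined
    PPV; both are reported as NaN rather than silent zeros.
    """
    if output.n_windows != labels.n_windows:
        raise ValueError("decoder output and labels are not aligned")
    known = labels.known()
    y = output.bits[known].astype(bool)
    s = labels.states[known]
    K = labels.K
    rows = []
    for k in range(1, K + 1):
        truth = s == k
        pred = y[:, k - 1]
        tp = int(np.sum(pred & truth))
        fn = int(np.sum(~pred & truth))
        fp = int(np.sum(pred & ~truth))
        tn = int(np.sum(~pred & ~truth))
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        ppv = tp / (tp + fp) if tp + fp else np.nan
        rows.append((k, sens, spec, ppv, tp, fn, fp, tn))
    return pd.DataFrame(
        rows,
        columns=["state", "sensitivity", "specificity", "ppv", "tp", "fn", "fp", "tn"],
    ).set_index("state")


def trajectory_correlation(decoded: StateSequence, truth: StateSequence) -> float:
    """Pearson correlation between decoded and true trajectories.

    Computed over windows labeled in both sequences, on segment-center
    positions when the segment length is known (an affine map of the indices,
    so r is identical either way).  NaN when fewer than two comparable windows
    remain or either sequence is constant.
    """
    if decoded.n_windows != truth.n_windows:
        raise ValueError("sequences are not aligned")
    mask = decoded.known() & truth.known()
    a = decoded.states[mask].astype(float)
    b = truth.states[mask].astype(float)
    if decoded.segment_length is not None:
        a = (a - 0.5) * decoded.segment_length
    if truth.segment_length is not None:
        b = (b - 0.5) * truth.segment_length
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b).statistic)


@dataclass
class LeaveOneOutResult:
    """Per-channel correlations after rate-matched noise substitution."""

    baseline_r: float
    per_channel_r: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_channel_r))

    @property
    def max_r(self) -> float:
        return float(np.max(self.per_channel_r))


def leave_one_out_eval(
    spikes: SpikeTrainSet,
    labels: StateSequence,
    config,
    seed: int,
    split_window: int | None = None,
) -> LeaveOneOutResult:
    """Channel-robustness harness: replace each channel in turn by a
    rate-matched random-time noise channel and re-run decode + smoothing on
    the test split.

    Templates and the confusion matrix are learned once, from the clean
    training split; only the test-split counts change per substitution.
    ``config`` is a :class:`~countdec.config.PipelineConfig`; ``seed`` drives
    the noise-channel draws.
    """
    from .pipeline import fit_decoder, smooth_and_score, split_index
    from .simulate import make_noise_channel

    if spikes.channel_count < 2:
        raise ValueError("leave-one-out needs at least 2 channels")
    if split_window is None:
        split_window = split_index(labels.n_windows, config)
    fitted = fit_decoder(spikes, labels, config, split_window)
    baseline = smooth_and_score(spikes, labels, config, fitted, split_window)
    rs = []
    for ch in range(spikes.channel_count):
        noisy = [t.copy() for t in spikes.spikes]
        noisy[ch] = make_noise_channel(noisy[ch], spikes.duration, seed + ch)
        sub = SpikeTrainSet(noisy, spikes.duration)
        rs.append(smooth_and_score(sub, labels, config, fitted, split_window))
    return LeaveOneOutResult(baseline_r=baseline, per_channel_r=np.array(rs))
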