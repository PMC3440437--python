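"""Statistical learning of the decoder program.

During a labeled training period, windowed spike counts are accumulated into
in-state and out-of-state frequency histograms per (state, channel).  Each
candidate spike-count threshold is scored by the sensitivity and positive
predictive value (PPV) with which "count >= threshold" discriminates the state
from its complement; a channel qualifies for a state when the lowest
qualifying threshold meets global (or per-state) minima, and the M most
informative qualifying channels become that state's template.

Sensitivity and specificity are properties of the decoding rule alone, while
PPV also depends on state occupancy; PPV here uses the empirical training
occupancies as class priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import (
    CountMatrix,
    StateSequence,
    Template,
    TemplateSet,
    counter_max,
)


@dataclass
class HistogramBank:
    """In-state (H) and out-of-state (H-bar) spike-count histograms.

    ``in_state[k-1, i-1, c]`` counts training windows labeled state ``k`` in
    which channel ``i`` registered ``c`` spikes; ``out_state`` counts windows
    carrying any other (known) label.  ``occupancy[k-1]`` is the number of
    windows labeled ``k``.
    """

    in_state: np.ndarray
    out_state: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        if self.in_state.shape != self.out_state.shape or self.in_state.ndim != 3:
            raise ValueError("in_state and out_state must be equal-shape K x N x 2^b")
        if self.occupancy.shape != (self.in_state.shape[0],):
            raise ValueError("occupancy must have one entry per state")

    @property
    def K(self) -> int:
        return self.in_state.shape[0]

    @property
    def n_channels(self) -> int:
        return self.in_state.shape[1]

    @property
    def counter_bits(self) -> int:
        return int(np.log2(self.in_state.shape[2]))


@dataclass
class LearnParams:
    """Template-learning configuration.

    ``sensitivity_min`` and ``ppv_min`` are the global minima a threshold must
    meet; ``per_state`` optionally overrides them for individual states as
    ``{state: (sensitivity_min, ppv_min)}``.  ``M`` caps the number of
    (channel, threshold) pairs kept per state.
    """

    sensitivity_min: float = 0.3
    ppv_min: float = 0.5
    M: int = 2
    counter_bits: int = 3
    per_state: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.sensitivity_min, self.ppv_min):
            if not 0.0 <= v <= 1.0:
                raise ValueError("sensitivity_min and ppv_min must lie in [0, 1]")
        if self.M < 0:
            raise ValueError("M must be >= 0")

    def minima_for(self, state: int) -> tuple[float, float]:
        return self.per_state.get(state, (self.sensitivity_min, self.ppv_min))


class ThresholdMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    ppv: float


def build_histograms(counts: CountMatrix, labels: StateSequence) -> HistogramBank:
    """Accumulate per-(state, channel) count histograms from labeled windows.

    Unknown-labeled windows are excluded entirely.
    """
    if counts.n_windows != labels.n_windows:
        raise ValueError(
            f"counts ({counts.n_windows} windows) and labels "
            f"({labels.n_windows}) are not aligned"
        )
    K, N = labels.K, counts.n_channels
    nbins = counter_max(counts.counter_bits) + 1
    known = labels.known()
    if not known.any():
        raise ValueError("all labels are unknown; nothing to learn from")
    per_state = np.zeros((K, N, nbins), dtype=int)
    c = counts.counts[known]
    s = labels.states[known] - 1
    for i in range(N):
        np.add.at(per_state[:, i, :], (s, c[:, i]), 1)
    occupancy = np.bincount(s, minlength=K)
    # out-of-state histogram = all labeled windows minus the in-state ones
    total = per_state.sum(axis=0, keepdims=True)
    out_state = np.broadcast_to(total, per_state.shape) - per_state
    return HistogramBank(per_state, out_state.copy(), occupancy)


def threshold_metrics(
    bank: HistogramBank, state: int, channel: int, threshold: int
) -> ThresholdMetrics:
    """Sensitivity, specificity and PPV of the rule "count >= threshold" for
    one (state, channel) pair, from the training histograms.

    PPV is NaN when the rule never fires in training (zero positive mass).
    """
    cmax = counter_max(bank.counter_bits)
    if not 1 <= threshold <= cmax:
        raise ValueError(f"threshold {threshold} outside 1..{cmax}")
    if bank.occupancy[state - 1] == 0:
        raise ValueError(f"state {state} unobserved in training")
    h = bank.in_state[state - 1, channel - 1]
    hbar = bank.out_state[state - 1, channel - 1]
    tp = h[threshold:].sum()
    fp = hbar[threshold:].sum()
    sens = tp / h.sum()
    spec = hbar[:threshold].sum() / hbar.sum() if hbar.sum() > 0 else np.nan
    ppv = tp / (tp + fp) if tp + fp > 0 else np.nan
    return ThresholdMetrics(float(sens), float(spec), float(ppv))


def select_threshold(
    bank: HistogramBank, state: int, channel: int, params: LearnParams
) -> int | None:
    """Lowest threshold meeting both the sensitivity and PPV minima for the
    given state, or None when no threshold qualifies."""
    smin, pmin = params.minima_for(state)
    cmax = counter_max(bank.counter_bits)
    for theta in range(1, cmax + 1):
        m = threshold_metrics(bank, state, channel, theta)
        if m.sensitivity >= smin and m.ppv >= pmin:
            return theta
    return None


def learn_templates(bank: HistogramBank, params: LearnParams) -> TemplateSet:
    """Learn one template per state: the M most informative qualifying
    (channel, threshold) pairs.

    Qualifying channels are ranked by PPV at their selected threshold, ties
    broken by sensitivity then by lower channel index.  States where no
    channel qualifies get an empty template (constant-0 output bit, resolved
    downstream by the trajectory smoother).
    """
    templates = []
    for k in range(1, bank.K + 1):
        if bank.occupancy[k - 1] == 0:
            templates.append(Template(state=k, entries=[]))
            continue
        qualifying = []
        for i in range(1, bank.n_channels + 1):
            theta = select_threshold(bank, k, i, params)
            if theta is None:
                continue
            m = threshold_metrics(bank, k, i, theta)
            qualifying.append((-m.ppv, -m.sensitivity, i, theta))
        qualifying.sort()
        entries = [(i, theta) for _, _, i, theta in qualifying[: params.M]]
        templates.append(Template(state=k, entries=entries))
    return TemplateSet(bank.K, params.M, bank.counter_bits, templates)


# -------------------------------------------------------------- bank CSV export


def write_histogram_bank(bank: HistogramBank, path) -> None:
    """Long-format CSV: state, channel, count, part (in|out), frequency."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# K={bank.K}\n# channels={bank.n_channels}\n")
        fh.write(f"# counter_bits={bank.counter_bits}\n")
        fh.write("state,channel,count,part,frequency\n")
        for part, arr in (("in", bank.in_state), ("out", bank.out_state)):
            for k in range(bank.K):
                for i in range(bank.n_channels):
                    for c, f in enumerate(arr[k, i]):
                        if f:
                            fh.write(f"{k + 1},{i + 1},{c},{part},{int(f)}\n")


def read_histogram_bank(path) -> HistogramBank:
    from .io import ParseError, _read_lines  # light reuse of the CSV plumbing

    meta, rows = _read_lines(path)
    K = int(meta["K"])
    N = int(meta["channels"])
    nbins = 1 << int(meta["counter_bits"])
    in_state = np.zeros((K, N, nbins), dtype=int)
    out_state = np.zeros((K, N, nbins), dtype=int)
    for lineno, row in rows:
        if row[0] == "state":
            continue
        if len(row) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 fields")
        k, i, c, part, f = row
        target = in_state if part == "in" else out_state
        target[int(k) - 1, int(i) - 1, int(c)] = int(f)
    occupancy = in_state[:, 0, :].sum(axis=1)
    return HistogramBank(in_state, out_state, occupancy)
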