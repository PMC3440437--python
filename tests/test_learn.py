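"""Histogram accumulation and threshold-template learning."""

import numpy as np
import pytest

from countdec import (
    CountMatrix,
    HistogramBank,
    LearnParams,
    StateSequence,
    build_histograms,
    learn_templates,
    select_threshold,
    threshold_metrics,
)


def make_bank(in_state, out_state):
    in_state = np.asarray(in_state)
    return HistogramBank(
        in_state, np.asarray(out_state), in_state[:, 0, :].sum(axis=1)
    )


def exhaustive_threshold_oracle(bank, state, channel, smin, pmin):
    """Independent scan over every threshold, recomputing the metrics from
    raw histogram mass."""
    h = bank.in_state[state - 1, channel - 1]
    hbar = bank.out_state[state - 1, channel - 1]
    for theta in range(1, h.size):
        tp, fp = h[theta:].sum(), hbar[theta:].sum()
        sens = tp / h.sum()
        ppv = tp / (tp + fp) if tp + fp else float("nan")
        if sens >= smin and ppv >= pmin:
            return theta
    return None


class TestBuildHistograms:
    def test_single_zero_count_window(self):
        counts = CountMatrix(np.zeros((1, 2), dtype=int), 0.25, 3)
        labels = StateSequence(np.array([2]), K=3)
        bank = build_histograms(counts, labels)
        assert bank.in_state[1, 0, 0] == 1 and bank.in_state[1, 1, 0] == 1
        assert bank.in_state.sum() == 2  # nothing else in-state
        # the window counts as out-of-state evidence for states 1 and 3 only
        assert bank.out_state[1].sum() == 0
        assert bank.out_state[0, 0, 0] == 1 and bank.out_state[2, 0, 0] == 1

    def test_hand_tabulated_six_windows(self):
        # windows: labels (1,1,2,2,0,1); channel counts below
        counts = CountMatrix(np.array([[3], [4], [0], [1], [7], [3]]), 0.25, 3)
        labels = StateSequence(np.array([1, 1, 2, 2, 0, 1]), K=2)
        bank = build_histograms(counts, labels)
        # state 1 in-state: counts 3,4,3 -> H(1,1,3)=2, H(1,1,4)=1
        assert bank.in_state[0, 0, 3] == 2 and bank.in_state[0, 0, 4] == 1
        # state 2 in-state: counts 0,1
        assert bank.in_state[1, 0, 0] == 1 and bank.in_state[1, 0, 1] == 1
        # unknown window (count 7) appears nowhere
        assert bank.in_state[:, 0, 7].sum() == 0
        assert bank.out_state[:, 0, 7].sum() == 0
        # out-of-state of 1 = in-state of 2 and vice versa (K=2)
        np.testing.assert_array_equal(bank.out_state[0], bank.in_state[1])
        np.testing.assert_array_equal(bank.out_state[1], bank.in_state[0])
        np.testing.assert_array_equal(bank.occupancy, [3, 2])

    def test_per_channel_mass_is_occupancy(self, rng):
        counts = CountMatrix(rng.integers(0, 8, (40, 5)), 0.25, 3)
        labels = StateSequence(rng.integers(0, 4, 40), K=3)
        bank = build_histograms(counts, labels)
        for i in range(5):
            np.testing.assert_array_equal(
                bank.in_state[:, i, :].sum(axis=1), bank.occupancy
            )

    def test_all_unknown_labels_rejected(self):
        counts = CountMatrix(np.zeros((3, 1), dtype=int), 0.25, 3)
        labels = StateSequence(np.zeros(3, dtype=int), K=2)
        with pytest.raises(ValueError, match="unknown"):
            build_histograms(counts, labels)

    def test_misaligned_inputs_rejected(self):
        counts = CountMatrix(np.zeros((3, 1), dtype=int), 0.25, 3)
        labels = StateSequence(np.array([1, 2]), K=2)
        with pytest.raises(ValueError, match="aligned"):
            build_histograms(counts, labels)


class TestThresholdMetrics:
    def perfectly_separated(self):
        K, N, nb = 2, 1, 8
        in_s = np.zeros((K, N, nb), dtype=int)
        out_s = np.zeros((K, N, nb), dtype=int)
        in_s[0, 0, 5] = 10  # state 1 always fires 5 spikes
        out_s[0, 0, 0] = 10  # everything else is silent
        in_s[1, 0, 0] = 10
        out_s[1, 0, 5] = 10
        return make_bank(in_s, out_s)

    def test_perfect_separation_gives_ones(self):
        m = threshold_metrics(self.perfectly_separated(), 1, 1, 1)
        assert m == (1.0, 1.0, 1.0)

    def test_identical_distributions_give_half_ppv(self):
        K, N, nb = 2, 1, 8
        h = np.zeros((K, N, nb), dtype=int)
        h[:, 0, 2] = 10
        bank = make_bank(h, h.copy())
        for theta in (1, 2):
            assert threshold_metrics(bank, 1, 1, theta).ppv == 0.5

    def test_toy_histograms_match_window_level_tally(self):
        """20 windows built explicitly; metrics from the histogram bank must
        equal a direct per-window confusion tally."""
        rng = np.random.default_rng(7)
        counts = CountMatrix(rng.integers(0, 8, (20, 1)), 0.25, 3)
        labels = StateSequence(rng.integers(1, 4, 20), K=3)
        bank = build_histograms(counts, labels)
        for theta in range(1, 8):
            pred = counts.counts[:, 0] >= theta
            truth = labels.states == 2
            tp = np.sum(pred & truth)
            fn = np.sum(~pred & truth)
            fp = np.sum(pred & ~truth)
            tn = np.sum(~pred & ~truth)
            m = threshold_metrics(bank, 2, 1, theta)
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
            assert m.specificity == pytest.approx(tn / (tn + fp))
            if tp + fp:
                assert m.ppv == pytest.approx(tp / (tp + fp))

    def test_unobserved_state_rejected(self):
        bank = self.perfectly_separated()
        bank.occupancy[0] = 0
        with pytest.raises(ValueError, match="unobserved"):
            threshold_metrics(bank, 1, 1, 1)


class TestSelectThreshold:
    def test_lowest_qualifying_threshold_wins(self):
        bank = TestThresholdMetrics().perfectly_separated()
        p = LearnParams(sensitivity_min=0.9, ppv_min=0.9, M=2, counter_bits=3)
        assert select_threshold(bank, 1, 1, p) == 1

    def test_unsatisfiable_minima_give_none(self):
        K, N, nb = 2, 1, 8
        h = np.zeros((K, N, nb), dtype=int)
        h[:, 0, 3] = 10
        bank = make_bank(h, h.copy())
        p = LearnParams(sensitivity_min=0.0, ppv_min=0.99, M=2, counter_bits=3)
        assert select_threshold(bank, 1, 1, p) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        in_s = rng.integers(0, 6, (3, 2, 8))
        out_s = rng.integers(0, 6, (3, 2, 8))
        in_s[:, :, 0] += 1  # ensure nonzero occupancy
        bank = make_bank(in_s, out_s)
        p = LearnParams(sensitivity_min=0.4, ppv_min=0.55, M=2, counter_bits=3)
        for k in (1, 2, 3):
            for i in (1, 2):
                assert select_threshold(bank, k, i, p) == exhaustive_threshold_oracle(
                    bank, k, i, 0.4, 0.55
                )


class TestLearnTemplates:
    def disjoint_bank(self, K=4):
        """One dedicated channel per state: channel k fires 5 spikes in state
        k and is silent otherwise."""
        nb = 8
        in_s = np.zeros((K, K, nb), dtype=int)
        out_s = np.zeros((K, K, nb), dtype=int)
        for k in range(K):
            for i in range(K):
                if i == k:
                    in_s[k, i, 5] = 10
                    out_s[k, i, 0] = 10 * (K - 1)
                else:
                    in_s[k, i, 0] = 10
                    out_s[k, i, 5] = 10
                    out_s[k, i, 0] = 10 * (K - 2)
        return make_bank(in_s, out_s)

    def test_degenerate_minima_keep_exactly_M(self):
        rng = np.random.default_rng(3)
        in_s = rng.integers(1, 6, (3, 5, 8))
        out_s = rng.integers(1, 6, (3, 5, 8))
        bank = make_bank(in_s, out_s)
        p = LearnParams(sensitivity_min=0.0, ppv_min=0.0, M=2, counter_bits=3)
        ts = learn_templates(bank, p)
        assert all(len(t.entries) == 2 for t in ts.templates)

    def test_dedicated_channels_recovered(self):
        bank = self.disjoint_bank()
        p = LearnParams(sensitivity_min=0.9, ppv_min=0.9, M=2, counter_bits=3)
        ts = learn_templates(bank, p)
        for k in range(1, 5):
            entries = ts.for_state(k)[0].entries
            assert [ch for ch, _ in entries] == [k]

    def test_template_invariants(self, rng):
        in_s = rng.integers(0, 6, (4, 6, 8))
        out_s = rng.integers(0, 6, (4, 6, 8))
        in_s[:, :, 1] += 1
        bank = make_bank(in_s, out_s)
        p = LearnParams(sensitivity_min=0.2, ppv_min=0.3, M=2, counter_bits=3)
        ts = learn_templates(bank, p)
        for t in ts.templates:
            assert len(t.entries) <= 2
            for ch, theta in t.entries:
                assert 1 <= ch <= 6 and 1 <= theta <= 7

    def test_emitted_threshold_is_minimal(self, rng):
        """For every learned (state, channel, theta), theta-1 must violate a
        constraint (or theta is already 1)."""
        in_s = rng.integers(0, 6, (4, 6, 8))
        out_s = rng.integers(0, 6, (4, 6, 8))
        in_s[:, :, 1] += 1
        bank = make_bank(in_s, out_s)
        p = LearnParams(sensitivity_min=0.4, ppv_min=0.5, M=3, counter_bits=3)
        ts = learn_templates(bank, p)
        for t in ts.templates:
            for ch, theta in t.entries:
                if theta == 1:
                    continue
                m = threshold_metrics(bank, t.state, ch, theta - 1)
                assert m.sensitivity < 0.4 or not m.ppv >= 0.5

    def test_raising_minima_never_adds_channels(self, rng):
        in_s = rng.integers(0, 6, (3, 8, 8))
        out_s = rng.integers(0, 6, (3, 8, 8))
        in_s[:, :, 2] += 1
        bank = make_bank(in_s, out_s)
        loose = LearnParams(0.2, 0.3, M=8, counter_bits=3)
        tight = LearnParams(0.5, 0.6, M=8, counter_bits=3)
        for k in (1, 2, 3):
            loose_ch = {c for c, _ in learn_templates(bank, loose).for_state(k)[0].entries}
            tight_ch = {c for c, _ in learn_templates(bank, tight).for_state(k)[0].entries}
            assert tight_ch <= loose_ch
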