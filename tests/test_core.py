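"""Windowed counting, trajectory discretization, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from countdec import (
    CountMatrix,
    DecoderOutput,
    SpikeTrainSet,
    StateSequence,
    Template,
    TemplateSet,
    UNKNOWN_STATE,
    counter_max,
    discretize_trajectory,
    window_counts,
)
from countdec import io as cio


def brute_force_counts(spikes, W, b, T):
    """Independent oracle: per-window bin counts over half-open windows."""
    out = np.zeros((T, spikes.channel_count), dtype=int)
    for i, times in enumerate(spikes.spikes):
        for t in range(T):
            n = np.sum((times >= t * W) & (times < (t + 1) * W))
            out[t, i] = min(n, counter_max(b))
    return out


class TestWindowCounts:
    def test_no_spikes_gives_zero_matrix(self):
        s = SpikeTrainSet([np.array([]), np.array([])], duration=1.0)
        cm = window_counts(s, 0.25, 3)
        assert cm.counts.shape == (4, 2)
        assert not cm.counts.any()

    def test_saturation_at_counter_max(self):
        s = SpikeTrainSet([np.linspace(0.01, 0.09, 10)], duration=0.5)
        cm = window_counts(s, 0.1, 3)
        assert cm.counts[0, 0] == 7  # 10 spikes, 3-bit counter saturates

    def test_boundary_spike_belongs_to_later_window(self):
        s = SpikeTrainSet([np.array([0.25])], duration=1.0)
        cm = window_counts(s, 0.25, 3)
        assert cm.counts[:, 0].tolist() == [0, 1, 0, 0]

    def test_zero_duration_is_an_error(self):
        s = SpikeTrainSet([np.array([])], duration=0.0)
        with pytest.raises(ValueError, match="no data"):
            window_counts(s, 0.25, 3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_binning_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = SpikeTrainSet(
            [np.sort(rng.uniform(0, 3.0, rng.integers(0, 80))) for _ in range(4)],
            duration=3.0,
        )
        cm = window_counts(s, 0.21, 3)
        np.testing.assert_array_equal(
            cm.counts, brute_force_counts(s, 0.21, 3, cm.n_windows)
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=0.999), max_size=40))
    def test_every_spike_in_exactly_one_window(self, times):
        """Window partition: with a wide counter, total counts equal total
        spikes (no loss, no double-counting)."""
        s = SpikeTrainSet([np.sort(np.array(times))], duration=1.0)
        cm = window_counts(s, 0.2, 12)
        assert cm.counts[:, 0].sum() == len(times)


class TestDiscretize:
    def test_left_edge_is_state_one(self):
        pairs = [(t, 0.0) for t in np.arange(0, 1.0, 0.05)]
        seq = discretize_trajectory(pairs, 3.5, 32, 0.25, duration=1.0)
        assert (seq.states == 1).all()

    def test_right_edge_clamps_to_K(self):
        pairs = [(t, 3.5) for t in np.arange(0, 1.0, 0.05)]
        seq = discretize_trajectory(pairs, 3.5, 32, 0.25, duration=1.0)
        assert (seq.states == 32).all()

    def test_sawtooth_matches_hand_binning(self):
        # 1 m track, K=4, W=1 s; one sample per window at 0.1, 0.3, 0.6, 0.9
        pairs = [(0.5, 0.1), (1.5, 0.3), (2.5, 0.6), (3.5, 0.9)]
        seq = discretize_trajectory(pairs, 1.0, 4, 1.0, duration=4.0)
        assert seq.states.tolist() == [1, 2, 3, 4]

    def test_unsampled_window_gets_unknown_sentinel(self):
        pairs = [(0.1, 0.5), (2.1, 0.5)]
        seq = discretize_trajectory(pairs, 1.0, 4, 1.0, duration=3.0)
        assert seq.states.tolist() == [3, UNKNOWN_STATE, 3]

    def test_invalid_K_rejected(self):
        with pytest.raises(ValueError):
            discretize_trajectory([(0.0, 0.0)], 1.0, 0, 0.25)


class TestInvariants:
    def test_count_matrix_rejects_values_beyond_counter(self):
        with pytest.raises(ValueError):
            CountMatrix(np.array([[8]]), 0.25, 3)

    def test_template_thresholds_bounded_by_counter(self):
        with pytest.raises(ValueError):
            TemplateSet(2, 2, 3, [Template(1, [(1, 8)])])

    def test_spike_times_must_be_sorted(self):
        with pytest.raises(ValueError, match="sorted"):
            SpikeTrainSet([np.array([0.5, 0.2])], duration=1.0)


class TestRoundTrips:
    def test_spike_trains(self, tmp_path, rng):
        s = SpikeTrainSet(
            [np.sort(rng.uniform(0, 2, 17)), np.array([]), np.array([1.5])],
            duration=2.0,
        )
        p = tmp_path / "s.csv"
        cio.write_spike_trains(s, p)
        s2 = cio.read_spike_trains(p)
        assert s2.duration == s.duration
        for a, b in zip(s.spikes, s2.spikes):
            np.testing.assert_allclose(a, b)

    def test_count_matrix(self, tmp_path, rng):
        cm = CountMatrix(rng.integers(0, 8, (13, 5)), 0.25, 3, start_time=1.5)
        p = tmp_path / "c.csv"
        cio.write_count_matrix(cm, p)
        cm2 = cio.read_count_matrix(p)
        np.testing.assert_array_equal(cm.counts, cm2.counts)
        assert (cm2.window_length, cm2.counter_bits, cm2.start_time) == (0.25, 3, 1.5)

    def test_state_sequence(self, tmp_path):
        seq = StateSequence(np.array([1, 0, 3, 3, 2]), K=4, segment_length=0.109375)
        p = tmp_path / "l.csv"
        cio.write_state_sequence(seq, p)
        seq2 = cio.read_state_sequence(p)
        np.testing.assert_array_equal(seq.states, seq2.states)
        assert seq2.K == 4 and seq2.segment_length == seq.segment_length

    def test_templates_json(self, tmp_path):
        ts = TemplateSet(
            4, 2, 3,
            [
                Template(1, [(1, 4)]),
                Template(2, [(2, 3), (5, 7)]),
                Template(2, [(3, 1)]),  # second template for the same state
                Template(4, []),
            ],
        )
        p = tmp_path / "rules.json"
        cio.write_templates(ts, p)
        ts2 = cio.read_templates(p)
        assert ts2.K == 4 and ts2.M == 2 and ts2.counter_bits == 3
        assert [(t.state, t.entries, t.op) for t in ts2.templates] == [
            (t.state, t.entries, t.op) for t in ts.templates
        ]

    def test_rule_table_csv(self, tmp_path):
        ts = TemplateSet(
            3, 2, 3, [Template(1, [(1, 4)]), Template(3, [(2, 3), (3, 1)])]
        )
        p = tmp_path / "table.csv"
        cio.export_rule_table_csv(ts, p)
        ts2 = cio.read_rule_table_csv(p)
        assert ts2.for_state(1)[0].entries == [(1, 4)]
        assert ts2.for_state(2) == []  # blank column
        assert ts2.for_state(3)[0].entries == [(2, 3), (3, 1)]

    def test_decoder_output(self, tmp_path, rng):
        y = DecoderOutput(rng.integers(0, 2, (9, 4)).astype(np.uint8), 0.25)
        p = tmp_path / "y.csv"
        cio.write_decoder_output(y, p)
        y2 = cio.read_decoder_output(p)
        np.testing.assert_array_equal(y.bits, y2.bits)
        assert y2.window_length == 0.25


class TestPrintedRuleTable:
    """The classic printed layout: state-indexed columns of c1, theta1, c2,
    theta2, with blanks where a state has fewer than two rules."""

    TABLE = (
        "# K=4\n# M=2\n# counter_bits=3\n"
        "row,1,2,3,4\n"
        "c1,1,1,10,15\n"
        "theta1,4,4,3,3\n"
        "c2,,3,29,16\n"
        "theta2,,3,4,3\n"
    )

    def test_parses_with_blanks(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(self.TABLE)
        ts = cio.read_rule_table_csv(p)
        assert ts.for_state(1)[0].entries == [(1, 4)]  # single-entry rule
        assert ts.for_state(2)[0].entries == [(1, 4), (3, 3)]
        assert all(len(t.entries) <= 2 for t in ts.templates)


class TestParseErrors:
    def test_bad_count_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "# window_length_s=0.25\n# counter_bits=3\nch1,ch2\n1,2\n9,0\n"
        )
        with pytest.raises(cio.ParseError, match=r"bad\.csv:5"):
            cio.read_count_matrix(p)

    def test_bad_channel_index_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# duration_s=1.0\n# channels=2\nchannel,time_s\n3,0.5\n")
        with pytest.raises(cio.ParseError, match=r"bad\.csv:4"):
            cio.read_spike_trains(p)

    def test_missing_metadata_is_descriptive(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("ch1\n0\n")
        with pytest.raises(cio.ParseError, match="window_length_s"):
            cio.read_count_matrix(p)
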