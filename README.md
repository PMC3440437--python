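# countdec

A counting-and-comparison neural decoder: an emulator of an implantable,
power-constrained decoding unit that infers discretized behavioral states
from multichannel spike trains using **no arithmetic beyond counting**,
paired with the external-unit algorithms that program it (statistical
threshold learning) and clean up its output (Viterbi trajectory smoothing).

It is written for researchers working on brain–machine interfaces and
low-power neural signal processing who want a faithful, testable software
model of threshold-template decoding — and for anyone decoding 1-D position
from hippocampal place-cell ensembles who wants a decoder whose implanted
half could plausibly run on a few thousand logic operations per second.

## The model

Spikes detected on each of *N* input channels are accumulated over
consecutive windows of length *W* in saturating *b*-bit counters, giving a
spike-count vector **x**(t) per window. The decoder's program is a set of
templates, at least one per state *k* ∈ {1, …, K}: each template stores up to
*M* pairs (cᵢ, θᵢ) of channel pointers and spike-count thresholds. The
internal unit's entire computation per window is

    Y_k(t) = 1   iff   x_{c_i}(t) ≥ θ_i  for every entry i of a template of state k

(the logical AND of the comparisons; states with several templates OR them).
The T×K binary matrix Y is the decoder's only output — K bits per window —
which is what makes the scheme a data compressor: an N-channel, B-bit,
f_s-Hz front end is reduced by a factor of N·B·f_s / (K/W).

**Learning.** During a labeled training period the external unit accumulates,
for every (state, channel), histograms of window counts in-state (H) and
out-of-state (H̄). For a candidate threshold θ,

* sensitivity = P(count ≥ θ | state k),
* PPV = P(state k | count ≥ θ) under the empirical occupancies,

and the template entry gets the *lowest* θ meeting global minima σ_min and
ρ_min on sensitivity and PPV; the M qualifying channels with the best PPV
(ties: sensitivity, then channel index) make up the state's template. The
same rules, viewed as a two-layer network of windowed integrate-and-fire
units with synaptic weights 1/θᵢ (per-synapse input capped at 1, firing level
= number of synapses), reproduce the decoder output bit for bit —
`emulate_if_network` proves this equivalence in the test suite.

**Smoothing.** The external unit treats the true state as hidden in a
discrete-time Markov chain. Emissions come from the training-period confusion
matrix Q, with Q[j, k] ≈ P(state j | bit k set) and set bits treated as
independent; transitions follow a diffusion-like prior
P(j→j′) ∝ exp(−d(j,j′)² / (2κτ)), where d is physical distance, κ a
diffusivity tied to movement speed, and τ the elapsed time since the last
nonzero output window. The Viterbi algorithm returns the single maximum a
posteriori trajectory.

## Worked example

Because suitable public recordings of this kind are scarce, the package
ships a synthetic generator emulating the target regime: place cells with
Gaussian receptive fields tiling a linear track, Poisson spiking, and
bidirectional traversals.

```sh
python examples/simulate_and_decode.py
```

simulates 32 place cells tiling 32 states of a 3.5 m track (250 ms windows,
3-bit counters, M = 2), learns templates and the confusion matrix from the
first two traversals, then decodes and smooths the remaining six. It prints:

```
states with learned rules : 30 / 32
train/test windows        : 268 / 840
test-split Pearson r      : 0.9976
compression factor        : 20000
```

Two states end up with no rule (no channel met both minima there) — the
smoother bridges them through the transition prior. The Pearson r compares
smoothed decoded position against true discretized position on held-out
traversals; the compression factor is the raw input bit rate (32 × 8 bits ×
10 kHz) over the output bit rate (32 bits / 250 ms).

The same pipeline is scriptable from the shell:

```sh
countdec run --seed 1 --out-dir run1
countdec decode --counts run1/counts.csv --rules run1/rules.json --out y.csv
countdec smooth --y y.csv --confusion run1/confusion.csv --kappa 0.01 \
    --segment-length 0.109375 --out path.csv
```

Other examples: `examples/learn_thresholds.py` (histogram → threshold
selection on a 12-window toy), `examples/spike_detection.py` (noise-multiple
detection on a synthetic waveform), `examples/compression_and_ops.py`
(resource models).

## Layout

| module | role |
| --- | --- |
| `countdec.core` | domain types, windowed saturating counting, trajectory discretization |
| `countdec.io` | delimited-text / JSON readers and writers for every artifact |
| `countdec.detect` | noise estimation and single-threshold spike detection |
| `countdec.learn` | histogram accumulation and threshold-template learning |
| `countdec.decoder` | internal-unit emulator + brute-force and integrate-and-fire oracles |
| `countdec.smoothing` | confusion matrix, diffusion transition prior, Viterbi |
| `countdec.simulate` | synthetic place-cell sessions, noise channels, raw waveforms |
| `countdec.metrics` | classification metrics, correlation, compression and op-count models |
| `countdec.pipeline` / `countdec.cli` | orchestration and the thin `countdec` command |
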