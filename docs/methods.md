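# Methods

This note documents the models implemented in `countdec`, the assumptions
behind them, the parameters that matter, and the choices made where the
design was genuinely open.

## Windowed counting

The decoder sees only windowed, saturating spike counts. Windows are
half-open, `[tW, (t+1)W)`: a spike exactly on a boundary belongs to the later
window, matching the semantics of counters that reset synchronously at the
window edge. Counters saturate at `2^b − 1` and never wrap; with the default
`b = 3` the representable range 0–7 matches the threshold range the rule
tables use. A trailing partial window is dropped (`T = floor(duration/W)`).
The window length `W` (default 250 ms) trades response latency against rate
estimation: longer windows average away Poisson variability and improve
interstate discriminability, at the cost of slower output and more training
data per histogram bin.

Channel and state indices are 1-based everywhere in the public API and on
disk, matching the convention of printed rule tables; NumPy axes are the only
0-based objects and conversion happens exactly where arrays are indexed.
Training windows without a position sample carry the unknown sentinel (0) and
are excluded from histogram accumulation and from all performance metrics.

## Spike detection

Detection is deliberately minimal — a single programmable threshold per
channel — because that is what a power-constrained front end can afford. The
noise scale per channel is the median absolute deviation scaled to the
Gaussian-equivalent standard deviation (×1.4826); the MAD is the standard
robust choice for spike-band noise because sparse large spikes barely move
the median, whereas they inflate the raw standard deviation. The automatic
threshold is `multiple × noise scale` with `multiple = 4.0` by default (a
conventional confidence bound for isolating events); `dead_time = 1 ms`
suppresses re-triggers within a spike's own width, and the default polarity
is negative, the extracellular convention. All three are configuration, not
science: real deployments tune them channel by channel.

## Template learning

For each (state k, channel i) the learner accumulates in-state and
out-of-state frequency histograms of the windowed counts, under the
approximation that the state is stationary within a window. The candidate
rule "count ≥ θ" is scored by

* sensitivity: in-state mass at or above θ over total in-state mass;
* specificity: out-of-state mass below θ over total out-of-state mass;
* PPV: in-state mass at or above θ over all mass at or above θ.

PPV uses the empirical training occupancies as class priors, since precision
necessarily depends on how often each state occurs. When the rule never
fires in training the PPV is undefined; it is reported as NaN and never
qualifies a threshold (a rule with no positive evidence should not be
programmed). The comparison is "≥" consistently in learning and decoding.

`select_threshold` returns the **lowest** θ meeting both minima — lowest
because sensitivity is non-increasing in θ, so the minimal qualifying
threshold is the most sensitive one that still satisfies the precision
constraint. The per-state template keeps the `M` qualifying channels ranked
by PPV at their selected threshold (ties: higher sensitivity, then lower
channel index). PPV leads the ranking because false positives are what the
downstream smoother has to clean up; the tie-breaks make learning
deterministic. States where no channel qualifies get an empty template and a
constantly-zero output bit — legal, logged, and resolved by the smoother
through the transition prior. The minima `σ_min = 0.3` and `ρ_min = 0.5` can
be overridden per state, the intended mechanism for forcing templates down
to ≤ M entries in hard states.

## The internal decoder and its two oracles

`decode` evaluates, per window, the AND of the stored comparisons for each
template and ORs templates of the same state. It is causal and memoryless by
construction — row t uses only window t. Two independent routes check it:

* `decode_full_oracle`: the unreduced form with a full K×N threshold array,
  equivalent whenever the reduced templates carry all channels;
* `emulate_if_network`: a two-layer integrate-and-fire network, one
  second-layer unit per template, synaptic weight 1/θᵢ, per-synapse input
  capped at 1, reset every window, firing level equal to the synapse count.
  The cap is what makes the equivalence exact: a capped term equals 1
  precisely when its channel attains threshold, so the accumulated value
  reaches the firing level only when every comparison passes. Without the
  cap, a plain weighted sum could reach the level with one strong channel
  compensating a weak one, which is not conjunction.

## Trajectory smoothing

The smoother is a hidden-Markov MAP decoder over the decoder's binary
output.

**Emissions.** `Q[j, k]`, estimated during training as the fraction of
bit-k-set windows whose true state was j (columns Laplace-smoothed with
pseudocount ε = 1 and normalized), is used directly as the per-bit factor;
set bits are treated as independent and an all-zero window contributes the
empty product, 1, for every state — silence is uninformative. Using the
posterior P(state | bit) as the likelihood factor is an approximation (it
folds in the training priors); it is adopted deliberately because it needs no
separate prior model and the Viterbi argmax is insensitive to per-window
constants.

**Transitions.** Physical continuity enters through a Gaussian,
diffusion-like prior `P(j→j′) ∝ exp(−d(j,j′)²/(2κτ))`, row-normalized. The
Gaussian form is the canonical diffusion kernel (and is configurable in
principle via the `TransitionModel` distances and kernel constant). κ has
units m²/s; the default 0.01 m²/s gives a one-window kernel scale of
`sqrt(κW)` = 5 cm, about half a segment at the default scenario's geometry —
tight enough to enforce continuity, loose enough to track 10 cm/s movement.
The elapsed-time clock τ resets to one window after every window with at
least one set bit and grows by one window per silent window, so the kernel
broadens across uninformative stretches exactly when the decoder has given
no evidence. One subtlety: in a row-stochastic kernel the *near* off-diagonal
entries are not monotone in τ (they overshoot the uniform limit 1/K and come
back down); the monotone content of "broadening" — self-transition mass
non-increasing, every off-diagonal-to-self ratio non-decreasing — is what the
tests assert.

**Viterbi.** Log-space recursion with backtracking, uniform initial
distribution (no reason to prefer a state before any evidence), argmax ties
broken toward the smaller state index for determinism. Transition matrices
are cached per distinct τ, so the cost is O(T·K²) with a handful of K×K
kernel evaluations.

## Resource models

The compression factor is the raw acquisition bit rate over the decoder
output bit rate, `N·B·f_s·W/K`; it is independent of how K and W covary at
fixed output rate.

The operation-count model tallies basic operations per computational frame
(one pass through all templates for one count vector). Each of the `K_T·M`
threshold comparisons costs one memory access (threshold + pointer fetch),
one multiplexer selection of the addressed counter, one comparison, `b_logic`
binary-logic operations folding the result into the template's AND, and one
template shift-register update; each frame additionally costs one
clock-counter operation and K output-register updates. Total load is the
frame rate times the per-frame sum. At the demonstrated configuration
(K_T = 32, M = 2, b_logic = 1, K = 32, 10 frames/s) this gives 353 operations
per frame and 3,530 per second. `b_logic` exceeds 1 only when richer
per-template logic (e.g. sum-of-products over level bands) replaces the
single comparison.

## Synthetic data: what it emulates and what it does not

The generator reproduces the structure of a linear-track place-cell session:

* behavior — alternating end-to-end traversals at per-traversal jittered
  speed (default 0.1 m/s ± 10%, 8 traversals of a 3.5 m track). The 0.1 m/s
  effective speed reflects that maze traversals for reward are slow on
  average; it yields ≈ 270 labeled training windows (two traversals), about
  8 per state, enough to populate 3-bit count histograms;
* encoding — one cell per state, Gaussian tuning with SD 0.10 m (≈ 25–30 cm
  fields), peak rate 20 Hz, baseline 0.2 Hz, typical of place cells on
  linear tracks; spiking is an inhomogeneous Poisson process generated by
  thinning;
* the evaluation fixtures — rate-matched noise channels (same event count,
  uniform random times) for the leave-one-out robustness harness, and raw
  waveforms (Gaussian noise + a stereotyped biphasic shape at known times)
  for the detection stage.

It deliberately omits theta-phase precession, bursting, cross-channel
correlation, multi-unit contamination, nonstationary fields, and 2-D arenas.
Passing the end-to-end test (Pearson r ≥ 0.8 on held-out traversals)
therefore shows the pipeline is correct and well-calibrated for
Poisson-place-field data; it does not by itself establish performance on
real recordings, where field overlap, correlated noise, and nonstationarity
are harsher.

The chronological train/test split (templates and confusion matrix learned
strictly from the traversals preceding the test period) mirrors how such a
system is actually programmed: learn first, then run.

## Numerical and degenerate-input conventions

* Saturation, never wraparound, in counters; count matrices with values
  beyond `2^b − 1` are rejected at construction and at parse time.
* Position exactly at the track end maps to state K (clamped), not K+1.
* Empty templates decode to constant 0; empty decoder rows emit probability
  1 for every state.
* A decoder bit never set in training makes its confusion column
  unnormalizable at ε = 0; this is an error rather than a silent fix, since
  ε > 0 is the intended remedy.
* Undefined metrics (sensitivity of an unlabeled state, PPV of a silent
  bit, correlation of a constant sequence) are NaN flags, never silent
  zeros.
* Pearson correlation is computed on segment-center positions when the
  segment length is known; this is an affine map of state indices, so r is
  unchanged — it simply keeps reported units physical.

## Known limitations

* Only the conjunction-of-at-least rule is implemented; the operation
  registry in `countdec.decoder` is the hook for level-band, silence, or
  sum-of-products rules, which the data model already admits.
* The smoother is offline (whole-record Viterbi); no fixed-lag streaming
  variant.
* The op-count model's per-frame accounting abstracts a specific
  register-level implementation; alternative microarchitectures would change
  the constants but not the `K_T·M`-dominated scaling.
* The leave-one-out harness perturbs the test split only, by design: it
  measures robustness of an already-programmed decoder, not of learning.
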