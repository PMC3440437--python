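"""External-unit trajectory smoothing: Viterbi over the decoder output.

The raw decoder bits are noisy, can flag several states at once, or none at
all.  Treating the true (discretized) position as the hidden state of a
discrete-time Markov chain, the smoother combines

* an emission model built from the decoder's training-period confusion
  matrix Q, where ``Q[j, k]`` estimates P(true state j | output bit k set),
  with set bits treated as independent so a window's emission factor is the
  product of ``Q[j, k]`` over its set bits (an empty product — an all-zero
  window — is uninformative and contributes 1 for every state); and

* a diffusion-like transition prior ``P(j -> j') ∝ exp(-d(j,j')² / (2 κ τ))``
  over physical inter-state distances d, which keeps self and nearest-neighbor
  moves most probable and broadens with the elapsed time τ since the last
  informative (nonzero) output window,

and returns the single maximum a posteriori state path via the Viterbi
recursion in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import UNKNOWN_STATE, DecoderOutput, StateSequence


@dataclass
class ConfusionMatrix:
    """Column-stochastic K x K matrix; Q[j, k] ≈ P(true state j | bit k set)."""

    Q: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        q = np.asarray(self.Q, dtype=float)
        if q.ndim != 2 or q.shape[0] != q.shape[1]:
            raise ValueError("Q must be square")
        if not np.allclose(q.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("columns of Q must sum to 1")
        self.Q = q

    @property
    def K(self) -> int:
        return self.Q.shape[0]


@dataclass
class TransitionModel:
    """Physical distances between states plus the diffusion constant κ.

    κ has units of m²/s and plays the role of a diffusivity: after an elapsed
    time τ the transition kernel has spatial scale sqrt(κ τ).  It is tied to
    the typical movement speed of the subject (κ ≈ (speed · scale)² / W).
    """

    distances: np.ndarray
    kappa: float
    window_length: float

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distances must be square")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("distances must be symmetric with zero diagonal")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        self.distances = d

    @property
    def K(self) -> int:
        return self.distances.shape[0]

    @classmethod
    def linear_track(
        cls, K: int, segment_length: float, kappa: float, window_length: float
    ) -> "TransitionModel":
        """Distances for K equal segments of a 1-D track: d(j,j') =
        |j - j'| · segment_length."""
        idx = np.arange(K)
        d = np.abs(idx[:, None] - idx[None, :]) * segment_length
        return cls(d, kappa, window_length)


def estimate_confusion(
    output: DecoderOutput, labels: StateSequence, pseudocount: float = 1.0
) -> ConfusionMatrix:
    """Empirical confusion matrix from a labeled training record.

    ``raw[j, k]`` counts windows in which bit k was set while the true state
    was j; columns are Laplace-smoothed by ``pseudocount`` and normalized.
    With ``pseudocount=0`` a bit that never fired leaves its column
    unnormalizable, which is an error.
    """
    if output.n_windows != labels.n_windows:
        raise ValueError("decoder output and labels are not aligned")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    K = labels.K
    if output.K != K:
        raise ValueError("decoder output width does not match K")
    known = labels.known()
    y = output.bits[known].astype(float)
    s = labels.states[known] - 1
    raw = np.zeros((K, K))
    np.add.at(raw, s, y)
    raw = raw + pseudocount
    colsum = raw.sum(axis=0)
    if np.any(colsum == 0):
        dead = int(np.flatnonzero(colsum == 0)[0]) + 1
        raise ValueError(
            f"decoder bit {dead} never set in training: column unnormalizable; "
            "use pseudocount > 0"
        )
    return ConfusionMatrix(raw / colsum, pseudocount)


def emission_prob(y_row: np.ndarray, state: int, Q: ConfusionMatrix) -> float:
    """Emission factor for one window: product of Q[state, k] over set bits k
    (1-based state); 1 when no bit is set."""
    y = np.asarray(y_row)
    return float(np.prod(Q.Q[state - 1, y == 1]))


def transition_matrix(model: TransitionModel, tau: float) -> np.ndarray:
    """Row-stochastic transition prior at elapsed time tau (>= one window)."""
    if tau < model.window_length:
        raise ValueError("tau must be at least one window length")
    logits = -(model.distances**2) / (2.0 * model.kappa * tau)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def viterbi(
    output: DecoderOutput, Q: ConfusionMatrix, model: TransitionModel
) -> StateSequence:
    """Maximum a posteriori state path for a decoder output record.

    Initial state distribution is uniform.  The elapsed-time clock τ resets to
    one window after every window with at least one set bit and grows by one
    window per all-zero window, so the transition prior broadens across
    uninformative stretches.  Computed in log space with backtracking; argmax
    ties break toward the smaller state index.
    """
    K = Q.K
    if model.K != K or output.K != K:
        raise ValueError("output, confusion matrix and transition model disagree on K")
    T = output.n_windows
    W = model.window_length
    y = output.bits
    with np.errstate(divide="ignore"):
        logQ = np.log(Q.Q)
    log_emit = y @ logQ.T  # (T, K); all-zero rows give the empty product, 0

    # elapsed-time clock, in whole windows, for the transition into window t
    tau_windows = np.ones(T, dtype=int)
    for t in range(1, T):
        tau_windows[t] = 1 if y[t - 1].any() else tau_windows[t - 1] + 1

    log_trans_cache: dict[int, np.ndarray] = {}

    def log_trans(nw: int) -> np.ndarray:
        if nw not in log_trans_cache:
            with np.errstate(divide="ignore"):
                log_trans_cache[nw] = np.log(transition_matrix(model, nw * W))
        return log_trans_cache[nw]

    delta = -np.log(K) + log_emit[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + log_trans(tau_windows[t])  # (from, to)
        back[t] = np.argmax(scores, axis=0)  # first max -> smaller index
        delta = scores[back[t], np.arange(K)] + log_emit[t]

    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    seg = model.distances[0, 1] if K > 1 else None
    return StateSequence(path + 1, K, segment_length=seg)


def viterbi_path_score(
    path: np.ndarray | StateSequence,
    output: DecoderOutput,
    Q: ConfusionMatrix,
    model: TransitionModel,
) -> float:
    """Log joint score of a given path under the smoother's model (uniform
    initial distribution); used for cross-checking against enumeration."""
    states = path.states if isinstance(path, StateSequence) else np.asarray(path)
    if np.any(states == UNKNOWN_STATE):
        raise ValueError("path must be fully labeled")
    y = output.bits
    T = y.shape[0]
    with np.errstate(divide="ignore"):
        logQ = np.log(Q.Q)
    log_emit = y @ logQ.T
    score = -np.log(Q.K) + log_emit[0, states[0] - 1]
    tau = 1
    for t in range(1, T):
        tau = 1 if y[t - 1].any() else tau + 1
        A = transition_matrix(model, tau * model.window_length)
        score += np.log(A[states[t - 1] - 1, states[t] - 1])
        score += log_emit[t, states[t] - 1]
    return float(score)
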