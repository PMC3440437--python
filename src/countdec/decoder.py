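"""The internal (implanted-unit) decoder: counting and comparison only.

At every window the spike-count vector is compared, component by component,
against each stored template; a state's output bit is set when all of its
template's thresholds are attained (logical AND), and states with several
templates OR their results.  ``decode_full_oracle`` is the unreduced
all-channel form and ``emulate_if_network`` realizes the same computation as a
two-layer network of windowed integrate-and-fire units — both serve as
independent cross-checks on ``decode``.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .core import (
    OP_CONJUNCTION,
    CountMatrix,
    DecoderOutput,
    Template,
    TemplateSet,
)

#: Registry of rule operations.  Only conjunction-of-at-least is implemented;
#: the registry is the hook for per-state operation selection (e.g. level-band
#: or silence rules) without changing the decoding loop.
RULE_OPS: dict[str, Callable[[np.ndarray, Template], np.ndarray]] = {}


def _register(name):
    def deco(fn):
        RULE_OPS[name] = fn
        return fn

    return deco


@_register(OP_CONJUNCTION)
def _conjunction_at_least(counts: np.ndarray, template: Template) -> np.ndarray:
    """Vectorized over windows: bit t = AND over entries of count >= theta."""
    if not template.entries:
        return np.zeros(counts.shape[0], dtype=np.uint8)
    bits = np.ones(counts.shape[0], dtype=bool)
    for ch, theta in template.entries:
        bits &= counts[:, ch - 1] >= theta
    return bits.astype(np.uint8)


def apply_template(count_vector: np.ndarray, template: Template) -> int:
    """Evaluate one template on one window's count vector; empty templates
    never fire."""
    op = RULE_OPS.get(template.op)
    if op is None:
        raise ValueError(f"unregistered rule operation {template.op!r}")
    return int(op(np.asarray(count_vector, dtype=int)[None, :], template)[0])


def decode(counts: CountMatrix, templates: TemplateSet) -> DecoderOutput:
    """Evaluate the T x K binary score matrix Y.

    Causal and memoryless: row t depends only on window t's counts.
    """
    if templates.max_channel() > counts.n_channels:
        raise ValueError(
            f"template references channel {templates.max_channel()} but the "
            f"count matrix has {counts.n_channels} channels"
        )
    bits = np.zeros((counts.n_windows, templates.K), dtype=np.uint8)
    for tpl in templates.templates:
        op = RULE_OPS.get(tpl.op)
        if op is None:
            raise ValueError(f"unregistered rule operation {tpl.op!r}")
        bits[:, tpl.state - 1] |= op(counts.counts, tpl)
    return DecoderOutput(bits, counts.window_length)


def decode_full_oracle(counts: CountMatrix, full_thresholds: np.ndarray) -> DecoderOutput:
    """Brute-force reference: the unreduced all-channel conjunction.

    ``full_thresholds`` is a K x N array; bit (t, k) is set iff
    ``counts[t, i] >= full_thresholds[k, i]`` for every channel i.
    """
    thr = np.asarray(full_thresholds, dtype=int)
    if thr.ndim != 2 or thr.shape[1] != counts.n_channels:
        raise ValueError("full_thresholds must be K x N")
    bits = np.all(counts.counts[:, None, :] >= thr[None, :, :], axis=2)
    return DecoderOutput(bits.astype(np.uint8), counts.window_length)


def emulate_if_network(counts: CountMatrix, templates: TemplateSet) -> DecoderOutput:
    """Decode via an equivalent two-layer integrate-and-fire network.

    Layer one is the N input channels; each layer-two unit connects to its
    template's channels with synaptic weight 1/threshold.  Over each window a
    unit integrates count/threshold per synapse, with the per-synapse
    contribution capped at 1, resets at the window boundary, and fires iff the
    accumulated value reaches the number of its synapses.  The cap makes the
    construction exactly equivalent to the conjunction rule: a capped term
    equals 1 precisely when its channel attains threshold, so the sum reaches
    the synapse count only when every comparison passes.
    """
    bits = np.zeros((counts.n_windows, templates.K), dtype=np.uint8)
    for tpl in templates.templates:
        if tpl.op != OP_CONJUNCTION:
            raise ValueError(
                "integrate-and-fire emulation supports only the conjunction rule"
            )
        if not tpl.entries:
            continue
        acc = np.zeros(counts.n_windows)
        for ch, theta in tpl.entries:
            acc += np.minimum(counts.counts[:, ch - 1] / theta, 1.0)
        bits[:, tpl.state - 1] |= (acc >= len(tpl.entries)).astype(np.uint8)
    return DecoderOutput(bits, counts.window_length)
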