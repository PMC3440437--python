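"""Learning a spike-count threshold from in/out-of-state histograms.

Builds a tiny labeled training record by hand, accumulates the per-(state,
channel) count histograms, and shows how the lowest threshold meeting the
sensitivity and positive-predictive-value minima is selected.
"""

import numpy as np

from countdec import (
    CountMatrix,
    LearnParams,
    StateSequence,
    build_histograms,
    learn_templates,
    select_threshold,
    threshold_metrics,
)

# 12 windows, 2 channels, 2 states.  Channel 1 fires ~5 spikes in state 1 and
# is nearly silent otherwise; channel 2 is uninformative noise.
counts = CountMatrix(
    np.array([[5, 2], [4, 0], [6, 3], [5, 1], [0, 2], [1, 0],
              [0, 3], [1, 1], [5, 2], [0, 0], [1, 2], [0, 1]]),
    window_length=0.25, counter_bits=3,
)
labels = StateSequence(np.array([1, 1, 1, 1, 2, 2, 2, 2, 1, 2, 2, 2]), K=2)

bank = build_histograms(counts, labels)
params = LearnParams(sensitivity_min=0.3, ppv_min=0.5, M=2, counter_bits=3)

theta = select_threshold(bank, state=1, channel=1, params=params)
m = threshold_metrics(bank, 1, 1, theta)
print(f"state 1 / channel 1: threshold = {theta} spikes per window")
print(f"  sensitivity = {m.sensitivity:.3f}  specificity = {m.specificity:.3f}"
      f"  ppv = {m.ppv:.3f}")

templates = learn_templates(bank, params)
for t in templates.templates:
    print(f"state {t.state}: entries = {t.entries}")

# The selected threshold is the LOWEST count that still meets both minima,
# maximizing sensitivity subject to the precision constraint.  Both channels
# qualify for state 1, but channel 1 discriminates better, so the ranking by
# ppv (then sensitivity) puts it first in the learned template.
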