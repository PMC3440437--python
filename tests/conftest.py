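import numpy as np
import pytest

from countdec import (
    PipelineConfig,
    fit_decoder,
    simulate_session,
    smooth_and_score,
    split_from_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scenario():
    """The reference synthetic scenario, simulated and fitted once: 32 place
    cells tiling 32 states, trained on the first traversal pair."""
    cfg = PipelineConfig(seed=1)
    traj, spikes, labels = simulate_session(cfg)
    split = split_from_trajectory(traj, cfg)
    fitted = fit_decoder(spikes, labels, cfg, split)
    r = smooth_and_score(spikes, labels, cfg, fitted, split)
    return {
        "config": cfg,
        "trajectory": traj,
        "spikes": spikes,
        "labels": labels,
        "split": split,
        "fitted": fitted,
        "r": r,
    }
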