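"""Pipeline configuration: one record holding every stage's parameters.

Defaults reproduce the package's reference scenario — 32 place cells tiling
32 states of a 3.5 m track, 250 ms windows, 3-bit counters, M = 2 thresholds
per template, sensitivity/PPV minima 0.3/0.5 — with all randomness funneled
through the single named seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import TrackConfig


@dataclass
class PipelineConfig:
    track: TrackConfig = field(default_factory=TrackConfig)
    field_width: float = 0.10  # place-field SD, m
    peak_rate: float = 20.0  # Hz at the field center
    baseline_rate: float = 0.2  # Hz far from the field
    n_cells: int | None = None  # default: one cell per state
    window_length: float = 0.25  # W, s
    counter_bits: int = 3  # b
    M: int = 2  # thresholds per template
    sensitivity_min: float = 0.3
    ppv_min: float = 0.5
    kappa: float = 0.01  # transition diffusivity, m^2/s
    pseudocount: float = 1.0  # Laplace smoothing of the confusion matrix
    train_traversals: int = 2  # chronological split: first traversal pair
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.track, dict):
            self.track = TrackConfig(**self.track)
        if self.window_length <= 0 or self.counter_bits < 1:
            raise ValueError("window_length must be positive and counter_bits >= 1")
        if not 0 <= self.sensitivity_min <= 1 or not 0 <= self.ppv_min <= 1:
            raise ValueError("sensitivity_min and ppv_min must lie in [0, 1]")
        if self.kappa <= 0 or self.pseudocount < 0:
            raise ValueError("kappa must be positive and pseudocount >= 0")
        if not 1 <= self.train_traversals < self.track.traversals:
            raise ValueError(
                "train_traversals must leave at least one traversal for testing"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path) -> None:
        if str(path).endswith((".yaml", ".yml")):
            Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
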