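"""Run configuration: one declarative object binding all pipeline stages.

Round-trips losslessly through YAML.  Defaults are the selected operating
point of the method: db1 / order 6 for the dual state-space models, db4 /
level 5 for the locality energies, bagged trees, 10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .classify import DEFAULT_CLASSIFIER
from .features import FeatureParams


@dataclass(frozen=True)
class RunConfig:
    channel: str = "EEG Pz-Oz"
    epoch_seconds: float = 30.0
    filter_cutoff_hz: float = 35.0
    filter_order: int = 8
    features: FeatureParams = field(default_factory=FeatureParams)
    classifier: str = DEFAULT_CLASSIFIER
    cv_folds: int = 10
    seed: int = 0
    standard: str = "R&K"
    n_classes: int = 6
    hypnogram_dialect: str = "edfplus"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"] = asdict(self.features)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "features" in d and isinstance(d["features"], dict):
            d["features"] = FeatureParams(**d["features"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
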