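"""Single-document pipeline configuration.

All pipeline constants live here with their published defaults so a
fidelity audit is a single diff: adipocyte gates (circularity 0.3, size
5 px, 50-iteration expansion over 5 passes), nucleated-cell detection
(0.5 µm working pixel, 8 µm background radius, 0 µm median, 1.5 µm
sigma, 10–400 µm² area gate, threshold 0.1, max background 2.0, 5 µm
expansion), the megakaryocyte filter (eccentricity 0.8, caliper 20 µm),
and the modelling stage (alpha 0.05, C 1.0, 5 folds × 5 repeats).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .featurebuild import FeatureConfig
from .imaging import DetectionParams

__all__ = ["ModelConfig", "PipelineConfig"]


@dataclass(frozen=True)
class ModelConfig:
    alpha: float = 0.05
    C: float = 1.0
    k: int = 5
    repeats: int = 5
    nested_selection: bool = False
    gmean_sqrt: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        return cls(
            detection=DetectionParams(**raw.get("detection", {})),
            features=FeatureConfig(**raw.get("features", {})),
            model=ModelConfig(**raw.get("model", {})),
        )

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
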