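"""One YAML-backed configuration governing all pipeline stages."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import FeatureConfig


@dataclass
class PipelineConfig:
    """Defaults are the balanced-cohort study conditions."""

    seed: int = 0
    subjects_per_class: int = 4
    videos_per_subject: int = 6
    frames_per_video: int = 5
    dtcwt_levels: int = 5
    k_features: int = 15
    chi2_bins: int = 10
    priors: str = "equal"            # equal | empirical
    scheme: str = "loo"              # loo | loso
    lda_ridge: float = 1e-6
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["features"]["glcm_offsets"] = [list(o) for o in
                                         self.features.glcm_offsets]
        d["features"]["glrlm_directions"] = list(
            self.features.glrlm_directions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        feat = d.pop("features", {})
        if feat:
            feat = dict(feat)
            if "glcm_offsets" in feat:
                feat["glcm_offsets"] = tuple(tuple(o)
                                             for o in feat["glcm_offsets"])
            if "glrlm_directions" in feat:
                feat["glrlm_directions"] = tuple(feat["glrlm_directions"])
            d["features"] = FeatureConfig(**feat)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
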