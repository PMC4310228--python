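"""Run configuration: one nested document covering every stage.

Unknown keys are rejected up front so a typo cannot silently fall back
to a default, and every run writes its resolved configuration next to
its outputs so results are reconstructible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import yaml

from .features import FeatureConfig
from .segmentation import SegmentationParams


@dataclass
class SimulateConfig:
    n_per_class: int = 70
    height: int = 128
    width: int = 128
    noise_sd: Optional[float] = None  # None -> per-preset default


@dataclass
class ClassifierConfig:
    id: str = "C1"
    C: float = 1.0
    scale: bool = True


@dataclass
class EvaluationConfig:
    folds: int = 10
    feature_sets: tuple[str, ...] = ("F1", "F2", "F3", "F4", "F5", "F6", "F7")


def _build(cls, d: dict, block: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown keys in '{block}' config: {sorted(unknown)}")
    return cls(**d)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "ntcc_out"
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        blocks = {
            "simulate": SimulateConfig,
            "segmentation": SegmentationParams,
            "features": FeatureConfig,
            "classifier": ClassifierConfig,
            "evaluation": EvaluationConfig,
        }
        kwargs: dict = {}
        for name, sub_cls in blocks.items():
            sub = d.pop(name, {})
            if not isinstance(sub, dict):
                raise ValueError(f"'{name}' must be a mapping")
            if name == "features" and "glcm_offsets" in sub:
                sub["glcm_offsets"] = tuple(tuple(o) for o in sub["glcm_offsets"])
            if name == "evaluation" and "feature_sets" in sub:
                sub["feature_sets"] = tuple(sub["feature_sets"])
            kwargs[name] = _build(sub_cls, sub, name)
        scalar = {f.name for f in dc_fields(cls)} - set(blocks)
        unknown = set(d) - scalar
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def write_resolved(self, out_dir: str | Path) -> Path:
        """Write the resolved config (plus tool version) into out_dir."""
        from . import __version__

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        doc = {"ntcc_version": __version__, **self.to_dict()}
        path = out / "resolved_config.json"
        path.write_text(json.dumps(doc, indent=2, default=list) + "\n")
        return path
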