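"""Pipeline configuration: one serializable object covering every stage.

Unknown keys are rejected on load so typos in config files fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Optional

import yaml

from . import constants as C
from .synthetic import SimConfig


@dataclass
class PreprocessConfig:
    eeg_fs_out: float = C.EEG_FS_OUT
    eeg_band_hz: tuple = C.EEG_BAND_HZ
    eeg_filter_order: int = C.EEG_FILTER_ORDER
    fnirs_band_hz: tuple = C.FNIRS_BAND_HZ
    fnirs_filter_order: int = C.FNIRS_FILTER_ORDER
    motion_window_s: float = C.MOTION_STD_WINDOW_S
    motion_k: float = C.MOTION_STD_K
    zero_phase: bool = True
    filter_before_downsample: bool = False


@dataclass
class SelectConfig:
    alpha: float = C.GLM_ALPHA
    contrast: tuple = (1.0, -1.0, 0.0)
    fallback: bool = False


@dataclass
class FeatureConfig:
    wavelet: str = C.DWT_WAVELET
    dwt_levels: int = C.DWT_LEVELS
    pca_components: int = C.PCA_COMPONENTS
    fold_safe: bool = False


@dataclass
class ClassifierConfig:
    C: float = C.SVM_C
    gamma: Optional[float] = None  # None → 1 / n_features


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    select: SelectConfig = field(default_factory=SelectConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _build(cls, d, path="")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def _build(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown config keys in {path or '<root>'}: {sorted(unknown)}")
    sections = _section_types(cls)
    kwargs = {}
    for name, val in d.items():
        if name in sections and isinstance(val, dict):
            kwargs[name] = _build(sections[name], val, path=f"{path}{name}.")
        elif isinstance(val, list) and _tuple_field(cls, name):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    return cls(**kwargs)


def _section_types(cls) -> dict:
    if cls is PipelineConfig:
        return {"sim": SimConfig, "preprocess": PreprocessConfig,
                "select": SelectConfig, "features": FeatureConfig,
                "classifier": ClassifierConfig}
    return {}


def _tuple_field(cls, name: str) -> bool:
    return name in ("eeg_band_hz", "fnirs_band_hz", "contrast")
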