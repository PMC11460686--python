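"""YAML configuration: one file with sections per pipeline stage.

Recognized sections: ``model``, ``protocol``, ``ga``, ``arrhythmia``,
``preprocess``, ``regression``.  Unknown keys raise early, at load time.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .calibration import GAConfig
from .features import ArrhythmiaThresholds
from .preprocess import PreprocessConfig

SECTIONS = ("model", "protocol", "ga", "arrhythmia", "preprocess", "regression")


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def _build(cls, section: dict | None, **overrides):
    section = dict(section or {})
    section.update({k: v for k, v in overrides.items() if v is not None})
    names = {f.name for f in fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "free_parameters" in section and section["free_parameters"] is not None:
        section["free_parameters"] = tuple(section["free_parameters"])
    if "bounds_log2" in section and section["bounds_log2"] is not None:
        section["bounds_log2"] = tuple(section["bounds_log2"])
    return cls(**section)


def ga_config(cfg: dict, **overrides) -> GAConfig:
    return _build(GAConfig, cfg.get("ga"), **overrides)


def arrhythmia_thresholds(cfg: dict, **overrides) -> ArrhythmiaThresholds:
    return _build(ArrhythmiaThresholds, cfg.get("arrhythmia"), **overrides)


def preprocess_config(cfg: dict, **overrides) -> PreprocessConfig:
    return _build(PreprocessConfig, cfg.get("preprocess"), **overrides)
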