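"""Key-value configuration: YAML sections mapped onto the config dataclasses.

Recognized sections and keys::

    embedder:
      backend: kmer_hash | plm     # default kmer_hash
      dim: 1024
      k: 3
      seed: 0
    model:        # ClassifierConfig fields
    loss:         # ASLConfig fields (gamma_pos, gamma_neg, mode, prob_floor)
    train:        # TrainConfig fields
    labels:       # LabelRuleSet overrides (lists of phrases)

Unknown keys raise, so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Any

import yaml

from .asl import ASLConfig
from .classifier import ClassifierConfig
from .core_io import FunctionalCategory, LabelRuleSet
from .embeddings import EmbedderBackend, KmerHashBackend
from .train_eval import TrainConfig


def load_config(path: str | Path) -> dict[str, Any]:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return data


def _build(cls, section: dict[str, Any] | None, what: str):
    section = dict(section or {})
    valid = {f.name for f in fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown {what} config keys: {sorted(unknown)}")
    return cls(**section)


def loss_config(config: dict[str, Any]) -> ASLConfig:
    return _build(ASLConfig, config.get("loss"), "loss")


def model_config(config: dict[str, Any]) -> ClassifierConfig:
    return _build(ClassifierConfig, config.get("model"), "model")


def train_config(config: dict[str, Any]) -> TrainConfig:
    return _build(TrainConfig, config.get("train"), "train")


def label_rules(config: dict[str, Any]) -> LabelRuleSet:
    section = dict(config.get("labels") or {})
    if "category_keywords" in section:
        section["category_keywords"] = {
            phrase: FunctionalCategory.from_name(name)
            for phrase, name in section["category_keywords"].items()
        }
    for key in ("structural_keywords", "nonstructural_keywords"):
        if key in section:
            section[key] = tuple(section[key])
    return _build(LabelRuleSet, section, "labels")


def embedder_backend(config: dict[str, Any]) -> EmbedderBackend:
    section = dict(config.get("embedder") or {})
    kind = section.pop("backend", "kmer_hash")
    if kind == "kmer_hash":
        return KmerHashBackend(
            dim=section.pop("dim", 1024),
            k=section.pop("k", 3),
            seed=section.pop("seed", 0),
            max_len=section.pop("max_len", 4000),
        )
    if kind == "plm":
        from .embeddings import TransformerBackend

        return TransformerBackend(**section)
    raise ValueError(f"unknown embedder backend {kind!r} (expected kmer_hash or plm)")
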