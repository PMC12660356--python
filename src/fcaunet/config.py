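"""Run configuration: nested YAML/JSON config with strict key checking.

A :class:`RunConfig` mirrors each pipeline stage's parameters.  Unknown
keys are rejected so typos fail loudly, and every defaulted value is
logged at startup.  A single global seed fans out deterministically to
per-stage seeds (a stable hash of the stage name mixed with the global
seed) so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml

log = logging.getLogger("fcaunet")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "runs/out"
    simulate: dict = field(default_factory=lambda: {
        "n_per_class": 30, "mode": "easy", "size": 64})
    preprocess: dict = field(default_factory=lambda: {
        "crop": False, "augment": False,
        "test_fraction": 0.2, "val_fraction": 0.2})
    enhance: dict = field(default_factory=lambda: {
        "method": "fce", "fe": 1.0, "fd": 2040.0,
        "clip": 0.2, "tile": [8, 8]})
    model: dict = field(default_factory=lambda: {
        "base_channels": 8, "depth": 4, "dropout_rate": 0.1,
        "attention_gate": "modified", "ffcm_enabled": True,
        "mask_head": False})
    train: dict = field(default_factory=lambda: {
        "epochs": 30, "batch_size": 8, "lr": 3e-3})
    evaluate: dict = field(default_factory=lambda: {
        "keep_fraction": 0.2, "k_folds": 5})


_STAGE_KEYS = {f.name: f for f in fields(RunConfig)}


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Read YAML (JSON fallback) and merge over defaults, strictly."""
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError:
            raw = json.loads(text)
    if overrides:
        raw.update(overrides)
    cfg = RunConfig()
    for key, value in raw.items():
        if key not in _STAGE_KEYS:
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(cfg, key)
        if isinstance(current, dict):
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            unknown = set(value) - set(current)
            if unknown:
                raise ValueError(f"unknown keys in config section {key!r}: {sorted(unknown)}")
            current.update(value)
        else:
            setattr(cfg, key, value)
    defaults = asdict(RunConfig())
    merged = asdict(cfg)
    for key, value in merged.items():
        if value == defaults[key]:
            log.info("config %-10s = %s (default)", key, value)
        else:
            log.info("config %-10s = %s", key, value)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:12]


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(asdict(cfg), sort_keys=False)
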