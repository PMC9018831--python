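"""Run configuration: feature-set presets, defaults, strict YAML parsing,
and JSON-lines structured logging shared by all commands."""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "validate_config", "FEATURE_SETS", "JsonLogger"]

#: feature-set presets by commonly available epigenomic assays
FEATURE_SETS: dict[int, tuple[str, ...]] = {
    13: (
        "ATAC-seq", "CTCF", "H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac", "H3K9me3",
        "H3K27ac", "H3K27me3", "H3K36me3", "H3K79me2", "Nanog", "Rad21",
    ),
    7: ("ATAC-seq", "CTCF", "H3K4me1", "H3K4me2", "H3K4me3", "H3K27ac", "H3K27me3"),
    6: ("ATAC-seq", "CTCF", "H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3"),
    3: ("ATAC-seq", "CTCF", "H3K27ac"),
}

KNOWN_FEATURES = set(FEATURE_SETS[13]) | {"DNase-seq"}

_DEFAULTS = dict(
    feature_set=6,
    features=None,            # explicit list overrides feature_set
    window_bp=250_000,
    step_bp=50_000,
    band_bp=200_000,
    resolution=200,
    encoding_dim=8,
    conv_channels=[32, 64],
    conv_kernels=[11, 5],
    gcn_units=[64, 64],
    embed_dim=64,
    lr=1e-3,
    epochs_loop=20,
    epochs_profile=30,
    loop_fdr=0.1,
    loop_fold=1.75,
    stripe_fold=2.0,
    stripe_min_length=10,
    seed=None,
)


@dataclass
class RunConfig:
    """Resolved run configuration with the 6-epi defaults filled in."""

    features: tuple[str, ...]
    window_bp: int = 250_000
    step_bp: int = 50_000
    band_bp: int = 200_000
    resolution: int = 200
    encoding_dim: int = 8
    conv_channels: tuple[int, ...] = (32, 64)
    conv_kernels: tuple[int, ...] = (11, 5)
    gcn_units: tuple[int, ...] = (64, 64)
    embed_dim: int = 64
    lr: float = 1e-3
    epochs_loop: int = 20
    epochs_profile: int = 30
    loop_fdr: float = 0.1
    loop_fold: float = 1.75
    stripe_fold: float = 2.0
    stripe_min_length: int = 10
    seed: int | None = None

    def require_seed(self, command: str) -> int:
        if self.seed is None:
            raise ValueError(f"command {command!r} is stochastic: config must set a seed")
        return int(self.seed)

    def as_dict(self) -> dict:
        return asdict(self)


def validate_config(path: str | Path | None) -> RunConfig:
    """Parse, validate and default-fill a YAML config file.

    Unknown keys and unknown feature names are rejected; ATAC-seq may be
    substituted by DNase-seq where requested.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**_DEFAULTS, **raw}
    features = merged.pop("features")
    feature_set = merged.pop("feature_set")
    if features is None:
        if feature_set not in FEATURE_SETS:
            raise ValueError(
                f"unknown feature_set {feature_set}; choose from {sorted(FEATURE_SETS)}"
            )
        features = FEATURE_SETS[feature_set]
    else:
        bad = [f for f in features if f not in KNOWN_FEATURES]
        if bad:
            raise ValueError(f"unknown features: {bad}; known: {sorted(KNOWN_FEATURES)}")
    for key in ("conv_channels", "conv_kernels", "gcn_units"):
        merged[key] = tuple(merged[key])
    return RunConfig(features=tuple(features), **merged)


class JsonLogger:
    """JSON-lines structured logger (the audit trail of every run)."""

    def __init__(self, stream=None):
        self.stream = stream or sys.stderr

    def log(self, event: str, **payload) -> None:
        rec = {"time": round(time.time(), 3), "event": event, **payload}
        self.stream.write(json.dumps(rec) + "\n")
        self.stream.flush()
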