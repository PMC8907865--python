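"""Run configuration: YAML loading, strict validation, defaulting, hashing.

A run is described by one nested mapping covering every stage.  Unknown
keys are rejected (typos must not silently fall back to defaults), every
omitted key takes its default, and the canonical JSON serialization of the
merged config is hashed so that artifact directories can record exactly
which configuration produced them.

The single global ``seed`` fans out to per-stage seeds through a stable
per-stage tag, so each stage is independently reproducible.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import zlib
from pathlib import Path
from typing import Any

import yaml

from .nets import ModelConfig
from .phantom import AtrophyParams, SyntheticCohortSpec
from .pwf import PWFParams
from .sr import SRConfig
from .train import TrainConfig

__all__ = ["ConfigError", "RunConfig", "load_config", "DEFAULTS"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "phantom": {
        "n_subjects": 20,
        "volume_shape": [24, 24, 12],
        "n_regions_per_slice": 4,
        "age_range": [63.0, 87.0],
        "visits_per_subject": [2, 5],
        "visit_spacing": 1.0,
        "spacing_jitter": 0.2,
        "diagnosis_probs": [0.28, 0.04, 0.54, 0.14],
        "kappas": [0.05, 0.12, 0.22, 0.35],
        "tau": 75.0,
        "s": 5.0,
        "noise_sd": 0.0,
    },
    "prep": {"T": 95, "A": 10, "c": 1.0, "radii": [1]},
    "model": {"image_size": 128, "latent_dim": 200, "base_channels": 8},
    "train": {"epochs": 300, "batch_size": 100, "lr": 0.0002, "beta1": 0.5,
              "common_init_iters": 100, "smoothing_sigma": 1.5,
              "smoothing_half_width": 2},
    "pwf": {"shapes": {"reg": 1.25, "vox": 1.25, "b": 0.002, "z": 0.05,
                       "rec": 100.0},
            "directions": {"reg": 1, "vox": 1, "b": 1, "z": 1, "rec": -1},
            "rho": 0.99, "v": 10.0},
    "sr": {"channels": 8, "n_dense_layers": 3, "epochs": 20, "patch_size": 8,
           "patches_per_pair": 8, "lr": 0.001, "max_pairs": 10},
    "simulate": {"personalize_iters": 50, "subject_id": None},
    "evaluate": {"threshold": 0.3},
    "gridsearch": {"epochs": 3, "draws": 8},
}


def _merge(defaults: Any, given: Any, path: str) -> Any:
    if isinstance(defaults, dict):
        if not isinstance(given, dict):
            raise ConfigError(f"{path or 'config'}: expected a mapping")
        unknown = set(given) - set(defaults)
        if unknown:
            raise ConfigError(f"unknown config key(s) at {path or 'top level'}: "
                              f"{sorted(unknown)}")
        merged = {}
        for k, dv in defaults.items():
            merged[k] = _merge(dv, given[k], f"{path}.{k}" if path else k) \
                if k in given else copy.deepcopy(dv)
        return merged
    return given


@dataclasses.dataclass(frozen=True)
class RunConfig:
    data: dict[str, Any]
    hash: str

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def stage_seed(self, tag: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        return int((int(self.data["seed"]) + zlib.crc32(tag.encode())) % 2 ** 31)

    # ----- typed views -------------------------------------------------------
    def cohort_spec(self) -> SyntheticCohortSpec:
        p = self.data["phantom"]
        atrophy = tuple(AtrophyParams(kappa=k, tau=p["tau"], s=p["s"])
                        for k in p["kappas"])
        return SyntheticCohortSpec(
            n_subjects=p["n_subjects"],
            volume_shape=tuple(p["volume_shape"]),
            n_regions_per_slice=p["n_regions_per_slice"],
            age_range=tuple(p["age_range"]),
            visits_per_subject=tuple(p["visits_per_subject"]),
            visit_spacing=p["visit_spacing"],
            spacing_jitter=p["spacing_jitter"],
            diagnosis_probs=tuple(p["diagnosis_probs"]),
            atrophy_params=atrophy,
            noise_sd=p["noise_sd"],
            seed=self.stage_seed("phantom"))

    def model_config(self) -> ModelConfig:
        m = self.data["model"]
        return ModelConfig(image_size=m["image_size"], latent_dim=m["latent_dim"],
                           n_age_bins=self.data["prep"]["A"],
                           base_channels=m["base_channels"],
                           seed=self.stage_seed("model"))

    def train_config(self) -> TrainConfig:
        t = self.data["train"]
        return TrainConfig(epochs=t["epochs"], batch_size=t["batch_size"],
                           lr=t["lr"], beta1=t["beta1"],
                           common_init_iters=t["common_init_iters"],
                           smoothing_sigma=t["smoothing_sigma"],
                           smoothing_half_width=t["smoothing_half_width"],
                           seed=self.stage_seed("train"))

    def pwf_params(self) -> PWFParams:
        p = self.data["pwf"]
        return PWFParams(shapes=dict(p["shapes"]),
                         directions={k: int(v) for k, v in p["directions"].items()},
                         rho=p["rho"], v=p["v"])

    def sr_config(self) -> SRConfig:
        s = self.data["sr"]
        return SRConfig(channels=s["channels"], n_dense_layers=s["n_dense_layers"],
                        epochs=s["epochs"], patch_size=s["patch_size"],
                        patches_per_pair=s["patches_per_pair"], lr=s["lr"],
                        seed=self.stage_seed("sr"))


def _hash(data: dict[str, Any]) -> str:
    blob = json.dumps(data, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> RunConfig:
    """Load, validate against the schema, default, and hash a run config.

    ``overrides`` is a (possibly nested) mapping applied on top of the file
    contents; an empty or missing file yields all defaults.
    """
    given: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        given = loaded
    if overrides:
        given = _apply_overrides(given, overrides)
    merged = _merge(DEFAULTS, given, "")
    return RunConfig(data=merged, hash=_hash(merged))


def _apply_overrides(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _apply_overrides(out[k], v)
        else:
            out[k] = v
    return out
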