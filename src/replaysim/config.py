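"""Structured run configuration: YAML in, fully resolved defaults out.

A run is described by nested sections (``dataset``, ``model``,
``optimizer``, ``replay``, ``augment``, ``protocol``) plus ``output_dir``
and ``master_seed``.  Every key has a default, unknown keys are rejected by
name, and the resolved configuration is serialized into each run manifest
so a run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import network, replay, synthetic
from .experiment import ProtocolConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Raised for unknown keys or badly typed config values."""


DEFAULTS: dict = {
    "master_seed": 0,
    "output_dir": "runs",
    "dataset": {
        "n_classes": 10,
        "n_train": 234,
        "n_val": 26,
        "n_test": 10,
        "image_size": 64,
        "seed": 0,
        "similarity_mode": "none",
        "difficulty_profile": [],
    },
    "model": {
        "preset": "mini",
        "pretrain_epochs": 5,
        "pretrain_classes": 20,
    },
    "optimizer": {
        "learning_rate": 3e-4,
        "batch_size": 36,
    },
    "replay": {
        "downsample_factors": dict(replay.DEFAULT_DOWNSAMPLE),
        "n_samples_per_class": None,
        "covariance_jitter": 1e-6,
        "clip_nonnegative": False,
    },
    "augment": {
        "max_rotation_deg": 20.0,
        "max_shift_frac": 0.2,
        "max_zoom_frac": 0.2,
        "horizontal_flip": True,
    },
    "protocol": {
        "condition": "generative",
        "cut_point": "pool_4",
        "n_days": 10,
        "n_models": 10,
        "exemplars_per_class": None,
    },
}


def _merge(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in user.items():
        path = f"{prefix}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown config key '{path}'")
        default = defaults[key]
        if isinstance(default, dict) and key != "downsample_factors":
            if not isinstance(value, dict):
                raise ConfigError(f"config key '{path}' must be a mapping")
            out[key] = _merge(default, value, prefix=f"{path}.")
        else:
            if default is not None and value is not None:
                if isinstance(default, bool) != isinstance(value, bool):
                    raise ConfigError(f"config key '{path}' has the wrong type")
                if isinstance(default, (int, float)) and not isinstance(value, (int, float)):
                    raise ConfigError(f"config key '{path}' must be numeric")
                if isinstance(default, str) and not isinstance(value, str):
                    raise ConfigError(f"config key '{path}' must be a string")
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Fully resolved configuration for one run."""

    raw: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    @property
    def master_seed(self) -> int:
        return int(self.raw["master_seed"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])

    def dataset_kwargs(self) -> dict:
        d = self.raw["dataset"]
        return dict(n_train=int(d["n_train"]), n_val=int(d["n_val"]),
                    n_test=int(d["n_test"]),
                    size=(int(d["image_size"]), int(d["image_size"])),
                    seed=int(d["seed"]))

    def prototypes(self) -> list[synthetic.CategoryPrototype]:
        d = self.raw["dataset"]
        return synthetic.generate_prototypes(
            int(d["n_classes"]), seed=int(d["seed"]),
            similarity_mode=d["similarity_mode"],
            difficulty_profile=d["difficulty_profile"] or None)

    def build_dataset(self) -> synthetic.DatasetBundle:
        return synthetic.build_dataset(self.prototypes(), **self.dataset_kwargs())

    def architecture(self) -> network.ArchitectureSpec:
        m = self.raw["model"]
        d = self.raw["dataset"]
        size = int(d["image_size"])
        if m["preset"] == "mini":
            return network.ArchitectureSpec.mini(n_outputs=int(d["n_classes"]),
                                                 input_shape=(size, size, 3))
        if m["preset"] == "vgg16":
            return network.ArchitectureSpec.vgg16(n_outputs=int(d["n_classes"]))
        raise ConfigError(f"unknown model preset '{m['preset']}'")

    def optimizer(self) -> network.OptimizerConfig:
        o = self.raw["optimizer"]
        return network.OptimizerConfig(learning_rate=float(o["learning_rate"]),
                                       batch_size=int(o["batch_size"]))

    def replay_config(self) -> replay.ReplayConfig:
        r = self.raw["replay"]
        n = r["n_samples_per_class"]
        return replay.ReplayConfig(
            downsample_factors={k: int(v) for k, v in r["downsample_factors"].items()},
            n_samples_per_class=None if n is None else int(n),
            covariance_jitter=float(r["covariance_jitter"]),
            clip_nonnegative=bool(r["clip_nonnegative"]))

    def augment_config(self) -> synthetic.AugmentConfig:
        a = self.raw["augment"]
        return synthetic.AugmentConfig(
            max_rotation_deg=float(a["max_rotation_deg"]),
            max_shift_frac=float(a["max_shift_frac"]),
            max_zoom_frac=float(a["max_zoom_frac"]),
            horizontal_flip=bool(a["horizontal_flip"]))

    def protocol(self, **overrides) -> ProtocolConfig:
        p = dict(self.raw["protocol"])
        m = self.raw["model"]
        p.update(overrides)
        ex = p.get("exemplars_per_class")
        return ProtocolConfig(
            condition=p["condition"], cut_point=p["cut_point"],
            n_days=int(p["n_days"]), n_models=int(p["n_models"]),
            exemplars_per_class=None if ex is None else int(ex),
            similarity_mode=self.raw["dataset"]["similarity_mode"],
            master_seed=int(p.get("master_seed", self.master_seed)),
            pretrain_epochs=int(m["pretrain_epochs"]),
            pretrain_classes=int(m["pretrain_classes"]))

    def to_manifest(self) -> dict:
        return copy.deepcopy(self.raw)


def load_config(path=None) -> RunConfig:
    """Load a YAML config; an absent/empty file resolves to all defaults."""
    user: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        user = loaded
    return RunConfig(raw=_merge(DEFAULTS, user))
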