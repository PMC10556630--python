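"""Configuration loading/validation, run manifests and checkpoints."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    pass


# key -> (expected type(s), default)
CONFIG_SCHEMA: dict[str, tuple] = {
    "task": (str, "chargrid6"),
    "model": (str, "guided"),
    "size": (str, "scaled"),
    "channels": (list, [8, 16, 16]),
    "embed_dim": (int, 12),
    "hidden_readout": (int, 64),
    "td_laterals": (bool, True),
    "loss_weights": (list, [1.0, 1.0, 1.0]),
    "optimizer": (str, "adam"),
    "lr": ((int, float), 0.002),
    "momentum": ((int, float), 0.9),
    "batch_size": (int, 32),
    "weight_decay": ((int, float), 0.0001),
    "max_epochs": (int, 60),
    "convergence_window": (int, 8),
    "convergence_threshold": ((int, float), 1.0),
    "folds": (int, 5),
    "seed": (int, 0),
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML config, fill defaults, reject unknown keys and wrong types
    (the error names the key and the expected type)."""
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
    raw.update(overrides or {})
    cfg = {}
    for key, val in raw.items():
        if key not in CONFIG_SCHEMA:
            raise ConfigError(f"unknown config key '{key}'")
        want, _default = CONFIG_SCHEMA[key]
        if not isinstance(val, want) or isinstance(val, bool) and want is int:
            names = want.__name__ if isinstance(want, type) else "/".join(t.__name__ for t in want)
            raise ConfigError(f"config key '{key}': expected {names}, got {type(val).__name__}")
        cfg[key] = val
    for key, (_want, default) in CONFIG_SCHEMA.items():
        cfg.setdefault(key, default)
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, command: str, config: dict, seeds: dict,
                   inputs: list | None = None, outputs: list | None = None) -> Path:
    """Write the run manifest: command, config snapshot, seeds, versions,
    timestamps, output paths and input checksums."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "versions": {"counterstream": __version__, "numpy": np.__version__},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": [str(p) for p in (outputs or [])],
        "input_checksums": {str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).is_file()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())


# --------------------------------------------------------------------------- checkpoints

def save_checkpoint(clf, path: str | Path) -> Path:
    """Single-file parameter archive plus a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **clf.net_.state_dict())
    params = clf.get_params()
    tc = params.pop("task_config")
    sidecar = {
        "estimator_params": params,
        "task_config": dataclasses.asdict(tc),
        "class_names": getattr(clf, "class_names_", None),
        "property_values": getattr(clf, "property_values_", None),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path):
    from .model import CounterstreamClassifier, CounterstreamNet, TaskConfig

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    tcd = sidecar["task_config"]
    tcd["image_shape"] = tuple(tcd["image_shape"])
    tc = TaskConfig(**tcd)
    params = sidecar["estimator_params"]
    for k in ("channels", "loss_weights"):
        if isinstance(params.get(k), list):
            params[k] = tuple(params[k])
    clf = CounterstreamClassifier(task_config=tc, **params)
    clf.net_ = CounterstreamNet(
        tc, mode=clf.mode, channels=clf.channels, embed_dim=clf.embed_dim,
        hidden_readout=clf.hidden_readout, td_laterals=clf.td_laterals,
        head_pool=clf.head_pool, seed=clf.random_state,
    )
    with np.load(path.with_suffix(".npz")) as data:
        clf.net_.load_state_dict({k: data[k] for k in data.files})
    clf.classes_ = np.arange(max(tc.answer_spaces.values()))
    if sidecar.get("class_names"):
        clf.class_names_ = sidecar["class_names"]
    if sidecar.get("property_values"):
        clf.property_values_ = sidecar["property_values"]
    return clf
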