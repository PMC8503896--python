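"""Run configuration: a flat YAML document with include support.

Every command that consumes a config file resolves it against the defaults
below and writes the fully-resolved document next to its outputs, so a run
is auditable from its artifacts alone.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "scene": {
        "kind": "nuclei",
        "height": 1024,
        "width": 1024,
        "density": None,   # None -> per-kind default
        "noise": 0.08,
    },
    "model": {
        "depth": 5,
        "base_width": 5,
        "widths": [5, 8, 16, 30, 62],
        "in_channels": 3,
        "out_channels": 2,
        "upsample_mode": "transposed",
        "norm_mode": "batch",
        "patch_size": 256,
    },
    "oracle": {
        "accept_threshold": 0.9,
        "correction_fidelity": 1.0,
        "seconds_per_manual_structure": 7.0,
        "seconds_per_accept": 1.0,
        "seconds_per_corrected_structure": 3.0,
        "train_seconds_per_patch_epoch": 0.5,
    },
    "schedule": {
        "patches_per_round": 3,
        "rounds": 3,
        "epochs_per_round": 8,
        "pretrain_epochs": 2,
        "reviews_per_round": None,
    },
    "thresholds": {
        "binarize": 0.5,
    },
    "projector": "pca",
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict:
    """Load a YAML config, resolving one level of ``include`` and defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    path = Path(path)
    doc = yaml.safe_load(path.read_text()) or {}
    if "include" in doc:
        base = load_config(path.parent / doc.pop("include"))
    else:
        base = copy.deepcopy(DEFAULTS)
    return _merge(base, doc)


def dump_config(cfg: dict, path=None) -> str:
    text = yaml.safe_dump(cfg, sort_keys=True, default_flow_style=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_config_from(cfg: dict):
    from .model import ModelConfig

    m = cfg["model"]
    widths = tuple(m["widths"]) if m.get("widths") else None
    return ModelConfig(depth=m["depth"], base_width=m["base_width"], widths=widths,
                       in_channels=m["in_channels"], out_channels=m["out_channels"],
                       upsample_mode=m["upsample_mode"], norm_mode=m["norm_mode"],
                       patch_size=m["patch_size"])


def oracle_config_from(cfg: dict):
    from .activeloop import CostModel, OracleConfig

    o = cfg["oracle"]
    cost = CostModel(
        seconds_per_manual_structure=o["seconds_per_manual_structure"],
        seconds_per_accept=o["seconds_per_accept"],
        seconds_per_corrected_structure=o["seconds_per_corrected_structure"],
        train_seconds_per_patch_epoch=o["train_seconds_per_patch_epoch"],
    )
    return OracleConfig(accept_threshold=o["accept_threshold"],
                        correction_fidelity=o["correction_fidelity"],
                        cost=cost, seed=cfg["seed"])


def schedule_from(cfg: dict):
    from .activeloop import Schedule

    s = cfg["schedule"]
    return Schedule(patches_per_round=s["patches_per_round"], rounds=s["rounds"],
                    epochs_per_round=s["epochs_per_round"],
                    pretrain_epochs=s["pretrain_epochs"],
                    reviews_per_round=s.get("reviews_per_round"))
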