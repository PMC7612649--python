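"""Model checkpointing.

Checkpoints are plain JSON: architecture, every parameter array, the time
scaler, the covariate standardisation statistics and the covariate names.
Floats are serialised with Python's shortest round-tripping repr, so a
save/load cycle reproduces predictions bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .hazard import HazardHead, HazardHeadConfig, TimeScaler
from .mixture import AssignmentNet, AssignmentNetConfig, MixtureModel

__all__ = ["CHECKPOINT_VERSION", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


def save_checkpoint(model: MixtureModel, path, meta: dict | None = None) -> None:
    head_cfg = model.heads[0].config
    payload = {
        "format_version": CHECKPOINT_VERSION,
        "head_config": {
            "n_layers": head_cfg.n_layers,
            "n_hidden": head_cfg.n_hidden,
            "latent_dim": head_cfg.latent_dim,
            "activation": head_cfg.activation,
        },
        "assign_config": {
            "n_layers": model.assignment.config.n_layers,
            "n_hidden": model.assignment.config.n_hidden,
            "dropout_rate": model.assignment.config.dropout_rate,
            "n_clusters": model.assignment.config.n_clusters,
        },
        "t_max": model.scaler.t_max,
        "covariate_names": model.covariate_names,
        "x_mean": model.x_mean.tolist(),
        "x_std": model.x_std.tolist(),
        "params": {k: v.tolist() for k, v in model.parameters().items()},
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> MixtureModel:
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupt checkpoint {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != CHECKPOINT_VERSION:
        raise ValueError(
            f"checkpoint format version {version} is not supported "
            f"(this build reads version {CHECKPOINT_VERSION})"
        )
    head_cfg = HazardHeadConfig(**payload["head_config"])
    assign_cfg = AssignmentNetConfig(**payload["assign_config"])
    scaler = TimeScaler(payload["t_max"])
    names = payload["covariate_names"]
    rng = np.random.default_rng(0)  # placeholder init; overwritten below
    heads = [HazardHead(head_cfg, scaler, rng)
             for _ in range(assign_cfg.n_clusters)]
    net = AssignmentNet(assign_cfg, len(names), rng)
    model = MixtureModel(heads, net, scaler, names,
                         x_mean=payload["x_mean"], x_std=payload["x_std"])
    try:
        model.set_parameters({k: np.array(v, dtype=float)
                              for k, v in payload["params"].items()})
    except KeyError as exc:
        raise ValueError(f"corrupt checkpoint {path}: missing {exc}") from exc
    return model
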