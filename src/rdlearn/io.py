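"""Checkpoint and run-configuration persistence.

Checkpoints are keyed-array containers (``.npz``) holding every parameter
and buffer tensor plus a JSON echo of the ModelSpec and input shape, so a
model can be rebuilt exactly without its training context.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .network import Network, build_model

__all__ = ["save_checkpoint", "load_checkpoint", "load_config"]


def save_checkpoint(path, net: Network, meta: dict | None = None) -> None:
    arrays = {f"state/{k}": v for k, v in net.state_dict().items()}
    arrays["spec_json"] = np.array(json.dumps(net.spec))
    arrays["input_shape"] = np.array(net.input_shape, dtype=np.intp)
    arrays["meta_json"] = np.array(json.dumps(meta or {}))
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[Network, dict]:
    with np.load(path, allow_pickle=False) as data:
        spec = json.loads(str(data["spec_json"]))
        input_shape = tuple(int(s) for s in data["input_shape"])
        net = build_model(spec, input_shape, seed=0)
        state = {
            k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")
        }
        net.load_state_dict(state)
        meta = json.loads(str(data["meta_json"]))
    return net, meta


def load_config(path) -> dict:
    """Read a YAML (or JSON) run configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg
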