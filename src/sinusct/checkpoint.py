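"""Model checkpoints: weights plus the embedded configuration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np


def save_checkpoint(model, cfg, path: str | Path) -> None:
    """Write an .npz with all parameters and a JSON-encoded config."""
    state = model.state_dict()
    cfg_json = json.dumps(dataclasses.asdict(cfg)) if dataclasses.is_dataclass(cfg) \
        else json.dumps(cfg)
    np.savez(str(path), __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    """Returns (config_dict, state_dict)."""
    with np.load(str(path)) as z:
        cfg = json.loads(bytes(z["__config__"].tobytes()).decode())
        state = {k: z[k] for k in z.files if k != "__config__"}
    return cfg, state


__all__ = ["save_checkpoint", "load_checkpoint"]
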