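"""Save/load trained model parameters.

Weights go into a numpy ``.npz`` archive next to a small JSON manifest
(architecture name, a hash of the parameter shapes, fold and seed), so a
stored model can be re-instantiated and verified against the data layout
it was trained for.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

__all__ = ["save_model", "load_model_into"]


def _shape_hash(params) -> str:
    desc = ";".join(f"{i}:{'x'.join(map(str, p.data.shape))}" for i, p in enumerate(params))
    return hashlib.sha256(desc.encode()).hexdigest()[:16]


def save_model(model, path, fold: int = 0, seed: int = 0) -> Path:
    """Write parameters to ``<path>.npz`` and a manifest to ``<path>.json``."""
    path = Path(path)
    params = model.parameters()
    np.savez(path.with_suffix(".npz"), **{f"p{i}": p.data for i in range(len(params)) for p in [params[i]]})
    manifest = {
        "architecture": getattr(model, "name", type(model).__name__),
        "input_shape": list(getattr(model, "input_shape", ())),
        "n_params": int(sum(p.data.size for p in params)),
        "shape_hash": _shape_hash(params),
        "fold": fold,
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return path.with_suffix(".npz")


def load_model_into(model, path):
    """Load stored parameters into a freshly constructed, matching model."""
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    params = model.parameters()
    if manifest["shape_hash"] != _shape_hash(params):
        raise ValueError(
            f"stored parameters ({manifest['architecture']}) do not match the "
            f"model's parameter shapes"
        )
    with np.load(path.with_suffix(".npz")) as data:
        for i, p in enumerate(params):
            p.data[...] = data[f"p{i}"]
    return model
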