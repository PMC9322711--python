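"""Model checkpoint serialization.

A checkpoint bundles the network weights with the architecture config and the
covariate-name manifest (plus the standardization table, if any) so that
predictions after reload are schema-safe.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .network import CounterfactualSurvivalNet, ModelConfig

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(path, net: CounterfactualSurvivalNet,
                    covariate_names: list[str],
                    scaler: pd.DataFrame | None = None,
                    meta: dict | None = None) -> None:
    path = Path(path)
    manifest = {
        "config": asdict(net.cfg),
        "m": net.m,
        "covariate_names": list(covariate_names),
        "scaler": None if scaler is None else {
            "index": list(scaler.index),
            "loc": scaler["loc"].tolist(),
            "scale": scaler["scale"].tolist(),
            "binary": scaler["binary"].astype(bool).tolist(),
        },
        "meta": meta or {},
    }
    arrays = {f"p{i}": arr for i, arr in enumerate(net.state_dict())}
    np.savez(path, manifest=json.dumps(manifest), **arrays)


def load_checkpoint(path) -> tuple[CounterfactualSurvivalNet, list[str],
                                   pd.DataFrame | None, dict]:
    with np.load(Path(path), allow_pickle=False) as archive:
        manifest = json.loads(str(archive["manifest"]))
        state = [archive[f"p{i}"] for i in range(len(archive.files) - 1)]
    cfg_dict = manifest["config"]
    cfg_dict["rep_layers"] = tuple(cfg_dict["rep_layers"])
    cfg_dict["branch_layers"] = tuple(cfg_dict["branch_layers"])
    cfg = ModelConfig(**cfg_dict)
    net = CounterfactualSurvivalNet(cfg, manifest["m"])
    net.load_state(state)
    scaler = None
    if manifest["scaler"] is not None:
        s = manifest["scaler"]
        scaler = pd.DataFrame({"loc": s["loc"], "scale": s["scale"],
                               "binary": s["binary"]}, index=s["index"])
    return net, manifest["covariate_names"], scaler, manifest["meta"]
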