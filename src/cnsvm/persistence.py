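"""Model bundle persistence.

A trained model is stored as a directory with a JSON manifest, the backbone
configuration and weights (flat ``.npz``), the standardisation statistics,
and — for hybrid models — the fitted SVM head and calibration via joblib.
"""

from __future__ import annotations

import dataclasses
import json
import os

import joblib
import numpy as np

from cnsvm.errors import FormatError
from cnsvm.model_core import InceptionConfig, ModelHandle, NetworkConfig, build_model
from cnsvm.svm_head import CNSVMModel, SVMHeadConfig

MANIFEST = "manifest.json"


def _config_to_dict(cfg: NetworkConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["modules"] = [dataclasses.asdict(m) for m in cfg.modules]
    return d


def _config_from_dict(d: dict) -> NetworkConfig:
    d = dict(d)
    d["modules"] = tuple(InceptionConfig(**m) for m in d["modules"])
    d["dense_widths"] = tuple(d["dense_widths"])
    d["dropout_rates"] = tuple(d["dropout_rates"])
    return NetworkConfig(**d)


def save_model(model: ModelHandle | CNSVMModel, directory: str | os.PathLike) -> None:
    """Write a backbone or hybrid model bundle."""
    os.makedirs(directory, exist_ok=True)
    is_hybrid = isinstance(model, CNSVMModel)
    backbone = model.backbone if is_hybrid else model

    arrays = {
        f"param_{i}": p.value for i, p in enumerate(backbone.network.params())
    }
    bn_states = [
        layer_state
        for layer_state in _batchnorm_states(backbone)
    ]
    for i, (mean, var) in enumerate(bn_states):
        arrays[f"bn_mean_{i}"] = mean
        arrays[f"bn_var_{i}"] = var
    if backbone.scaler_mean is not None:
        arrays["scaler_mean"] = backbone.scaler_mean
        arrays["scaler_sd"] = backbone.scaler_sd
    np.savez(os.path.join(directory, "backbone.npz"), **arrays)

    manifest = {
        "format": "cnsvm-bundle-v1",
        "hybrid": is_hybrid,
        "seed": backbone.seed,
        "network_config": _config_to_dict(backbone.config),
        "components": ["backbone.npz"],
    }
    if is_hybrid:
        joblib.dump(
            {"head": model.head, "calibration": model.calibration,
             "cv_accuracy": model.cv_accuracy},
            os.path.join(directory, "head.joblib"),
        )
        manifest["head_config"] = dataclasses.asdict(model.head_config)
        manifest["components"].append("head.joblib")
    with open(os.path.join(directory, MANIFEST), "w") as fh:
        json.dump(manifest, fh, indent=2)


def _batchnorm_layers(backbone: ModelHandle):
    from cnsvm.nnet import BatchNorm, InceptionModule

    for layer in backbone.network.feature_layers:
        if isinstance(layer, InceptionModule):
            for branch in layer.branches:
                for sub in branch:
                    if isinstance(sub, BatchNorm):
                        yield sub
        elif isinstance(layer, BatchNorm):
            yield layer


def _batchnorm_states(backbone: ModelHandle):
    for bn in _batchnorm_layers(backbone):
        yield bn.running_mean, bn.running_var


def load_model(directory: str | os.PathLike) -> ModelHandle | CNSVMModel:
    """Read a bundle written by :func:`save_model`."""
    manifest_path = os.path.join(directory, MANIFEST)
    if not os.path.exists(manifest_path):
        raise FormatError(f"{directory}: no {MANIFEST}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "cnsvm-bundle-v1":
        raise FormatError(f"{directory}: unrecognised bundle format")

    cfg = _config_from_dict(manifest["network_config"])
    backbone = build_model(cfg, seed=manifest.get("seed", 0))
    with np.load(os.path.join(directory, "backbone.npz")) as arrays:
        for i, p in enumerate(backbone.network.params()):
            stored = arrays[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise FormatError(f"{directory}: weight {i} shape mismatch")
            p.value = stored
        for i, bn in enumerate(_batchnorm_layers(backbone)):
            bn.running_mean = arrays[f"bn_mean_{i}"]
            bn.running_var = arrays[f"bn_var_{i}"]
        if "scaler_mean" in arrays:
            backbone.scaler_mean = arrays["scaler_mean"]
            backbone.scaler_sd = arrays["scaler_sd"]

    if not manifest["hybrid"]:
        return backbone
    head_bundle = joblib.load(os.path.join(directory, "head.joblib"))
    return CNSVMModel(
        backbone=backbone,
        head=head_bundle["head"],
        head_config=SVMHeadConfig(**manifest["head_config"]),
        calibration=head_bundle["calibration"],
        cv_accuracy=head_bundle["cv_accuracy"],
    )
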