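"""Self-describing model checkpoints.

A checkpoint is a single ``.npz`` archive holding every parameter array plus a
JSON header with the backbone spec, seeds, RFF parameters / Laplace precision
(for SNGP models) and any training metadata the caller wants to attach. It is
sufficient to rebuild the model for evaluation-only use without retraining.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .uq_models import (
    BackboneSpec,
    MlpClassifier,
    ResidualMlp,
    SngpClassifier,
    TransformerClassifier,
    _SpectralTransformerBackbone,
)

__all__ = ["save_checkpoint", "load_checkpoint"]


def _model_header(model) -> dict:
    if isinstance(model, MlpClassifier):
        return {"kind": "mlp", "spec": vars(model.spec),
                "n_in": model.backbone.layers[0].w.shape[0], "seed": model.seed}
    if isinstance(model, TransformerClassifier):
        return {"kind": "transformer",
                "spec": vars(model.spec),
                "d_in": model.backbone.input_proj.w.shape[0], "seed": model.seed}
    if isinstance(model, SngpClassifier):
        bb = model.backbone
        if isinstance(bb, _SpectralTransformerBackbone):
            backbone = {"kind": "spectral_transformer",
                        "d_in": bb.input_proj.w.shape[0],
                        "depth": bb.depth, "width": bb.width,
                        "heads": bb.blocks[0].h,
                        "spectral_bound": bb.input_proj.spectral_bound}
        elif isinstance(bb, ResidualMlp):
            backbone = {"kind": "residual_mlp",
                        "n_in": bb.input_proj.w.shape[0],
                        "depth": bb.depth, "width": bb.width,
                        "spectral_bound": bb.spectral_bound}
        else:
            raise TypeError(f"cannot checkpoint backbone {type(bb).__name__}")
        return {"kind": "sngp", "backbone": backbone, "seed": model.seed,
                "rff_dim": model.rff_dim, "length_scale": model.length_scale,
                "hidden_norm": model.hidden_norm,
                "mean_field_lambda": model.mean_field_lambda}
    raise TypeError(f"cannot checkpoint {type(model).__name__}")


def save_checkpoint(model, path: str | Path, metadata: dict | None = None) -> None:
    header = _model_header(model)
    if metadata:
        header["metadata"] = metadata
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params)}
    if isinstance(model, SngpClassifier):
        arrays["precision"] = model.precision
        arrays["rff_w"] = model.rff_w
        arrays["rff_b"] = model.rff_b
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
             **arrays)


def _rebuild(header: dict):
    kind = header["kind"]
    if kind == "mlp":
        spec = BackboneSpec(**header["spec"])
        return MlpClassifier(header["n_in"], spec, seed=header["seed"])
    if kind == "transformer":
        spec = BackboneSpec(**header["spec"])
        return TransformerClassifier(header["d_in"], spec, seed=header["seed"])
    if kind == "sngp":
        bb = header["backbone"]
        if bb["kind"] == "residual_mlp":
            backbone = ResidualMlp(bb["n_in"], bb["width"], bb["depth"],
                                   seed=header["seed"],
                                   spectral_bound=bb["spectral_bound"])
        else:
            spec = BackboneSpec("transformer", bb["depth"], bb["width"],
                                heads=bb["heads"])
            backbone = _SpectralTransformerBackbone(
                bb["d_in"], spec, seed=header["seed"],
                spectral_bound=bb["spectral_bound"] or 0.95)
        return SngpClassifier(backbone, rff_dim=header["rff_dim"],
                              length_scale=header["length_scale"],
                              seed=header["seed"],
                              mean_field_lambda=header["mean_field_lambda"],
                              hidden_norm=header["hidden_norm"])
    raise ValueError(f"unknown checkpoint kind {kind!r}")


def load_checkpoint(path: str | Path):
    """Rebuild a model for evaluation from a checkpoint archive."""
    with np.load(path) as archive:
        header = json.loads(bytes(archive["header"]).decode())
        model = _rebuild(header)
        for i, p in enumerate(model.params):
            data = archive[f"param_{i}"]
            if data.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch in {path}")
            p.data = data.copy()
        if isinstance(model, SngpClassifier):
            model.rff_w = archive["rff_w"].copy()
            model.rff_b = archive["rff_b"].copy()
            model.precision = archive["precision"].copy()
            model._cho = None
    return model
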