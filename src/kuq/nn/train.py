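"""Adam training with early stopping for binary classifiers.

A "model" here is any object exposing `params` (list of Tensors),
`forward_logits(*inputs) -> Tensor`, and an optional `project()` hook that is
called after every optimizer step (used for spectral-norm constraints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .layers import Adam

__all__ = ["TrainConfig", "TrainHistory", "train_model", "bce_with_logits"]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    batch_size: int | None = None  # None = full batch
    seed: int = 0


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def __len__(self) -> int:
        return len(self.val_loss)


def bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable via softplus."""
    y = np.asarray(y, dtype=float)
    return (logits.softplus() - logits * y).mean()


def _take(inputs: tuple, idx) -> tuple:
    return tuple(np.asarray(a)[idx] for a in inputs)


def train_model(model, train_data, val_data, config: TrainConfig) -> TrainHistory:
    """Train `model` on binary labels with Adam and early stopping.

    `train_data`/`val_data` are `(inputs, y)` where `inputs` is a tuple of
    arrays whose first axis indexes samples (e.g. `(X,)` for an MLP,
    `(X, mask)` for a transformer). Stops when validation loss has not
    improved for `patience` epochs and restores the best-validation
    parameters. Deterministic for a fixed config seed.
    """
    (tr_inputs, tr_y) = train_data
    (va_inputs, va_y) = val_data
    tr_y = np.asarray(tr_y, dtype=float)
    va_y = np.asarray(va_y, dtype=float)
    for y, name in ((tr_y, "training"), (va_y, "validation")):
        if np.unique(y).size < 2 and name == "training":
            raise ValueError("training split must contain both classes")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, lr=config.lr)
    n = len(tr_y)
    history = TrainHistory()
    best_val = np.inf
    best_state = [p.data.copy() for p in model.params]
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        bs = config.batch_size or n
        epoch_losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            opt.zero_grad()
            logits = model.forward_logits(*_take(tr_inputs, idx))
            loss = bce_with_logits(logits, tr_y[idx])
            loss.backward()
            opt.step()
            if hasattr(model, "project"):
                model.project()
            epoch_losses.append(float(loss.data))
        val_logits = model.forward_logits(*va_inputs)
        val_loss = float(bce_with_logits(val_logits, va_y).data)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_state = [p.data.copy() for p in model.params]
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    for p, s in zip(model.params, best_state):
        p.data = s
    if hasattr(model, "finalize"):
        model.finalize(tr_inputs)
    return history
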