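"""Training regime: Adam, early stopping, checkpointing, grid search.

Batches are built from windows ordered by (participant, start day) so that
consecutive rows of a batch are time-adjacent windows of the same participant
— the pairing the smoothness penalty needs at horizon 1. The batch *order* is
shuffled every epoch; rows within a batch are not.

Early stopping monitors the composite validation loss (smoothness term
included, so model selection optimizes the training objective) with a
configurable patience, and the parameters from the best validation epoch are
the ones returned and checkpointed.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .his_model import (
    ModelConfig,
    ModelParams,
    composite_loss_segmented,
    flatten_params,
    forward_backward,
    init_params,
    predict,
    save_checkpoint,
    unflatten_params,
)
from .preprocessing import WindowedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainState",
    "GridSpec",
    "train",
    "early_stopping_update",
    "grid_search",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and stopping hyperparameters (defaults per the selected
    operating point: Adam at 1e-3, batches of 64, patience 10)."""

    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 10
    min_delta: float = 0.0
    seed: int = 0
    smoothness_weight: float | None = None  # overrides ModelConfig when set
    checkpoint_path: str | None = None
    log_path: str | None = None

    def validate(self) -> None:
        if self.patience < 1:
            raise ValueError(f"patience must be >= 1, got {self.patience}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainState:
    """Mutable early-stopping bookkeeping plus loss history."""

    epoch: int = 0
    train_history: list[float] = field(default_factory=list)
    val_history: list[float] = field(default_factory=list)
    best_val_loss: float = math.inf
    best_epoch: int = 0
    epochs_since_improvement: int = 0
    stopped_early: bool = False


def early_stopping_update(
    state: TrainState,
    val_loss: float,
    patience: int,
    min_delta: float = 0.0,
) -> TrainState:
    """Advance the early-stopping state by one epoch's validation loss.

    Improvement means val_loss < best − min_delta; it resets the counter and
    records the epoch, otherwise the counter increments and the stop flag is
    raised once it reaches ``patience``.
    """
    state.epoch += 1
    state.val_history.append(float(val_loss))
    if val_loss < state.best_val_loss - min_delta:
        state.best_val_loss = float(val_loss)
        state.best_epoch = state.epoch
        state.epochs_since_improvement = 0
    else:
        state.epochs_since_improvement = state.epoch - state.best_epoch
        if state.epochs_since_improvement >= patience:
            state.stopped_early = True
    return state


# --------------------------------------------------------------------------
# Adam on the flattened parameter vector
# --------------------------------------------------------------------------

class _Adam:
    def __init__(self, n: int, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, theta: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return theta - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _ordered(ds: WindowedDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sort windows by (participant, start day); return X, y, segment labels."""
    order = sorted(range(ds.n_windows), key=lambda i: ds.index[i])
    X = ds.inputs[order]
    y = ds.targets[order]
    seg = np.array([ds.index[i][0] for i in order])
    return X, y, seg


def _val_loss(params, config, X, y, seg) -> float:
    pred = predict(X, params, config).y.reshape(-1, config.horizon)
    lam = config.smoothness_weight
    if config.horizon == 1:
        return float(composite_loss_segmented(y, pred, lam, seg))
    from .his_model import composite_loss
    return float(composite_loss(y, pred, lam))


def train(
    train_ds: WindowedDataset,
    val_ds: WindowedDataset,
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
    init: ModelParams | None = None,
) -> tuple[ModelParams, TrainState]:
    """Minimize the composite loss with Adam and patience-based stopping.

    Returns the parameters from the best-validation-loss epoch together with
    the full training state. Deterministic under (seed, data) in this
    single-threaded implementation. A non-finite loss aborts with the epoch,
    batch and learning rate in the message.
    """
    train_config.validate()
    model_config.validate()
    if train_ds.n_windows == 0 or val_ds.n_windows == 0:
        raise ValueError("train and validation splits must both be non-empty")
    if train_config.smoothness_weight is not None:
        model_config = replace(model_config, smoothness_weight=train_config.smoothness_weight)

    Xtr, ytr, seg_tr = _ordered(train_ds)
    Xva, yva, seg_va = _ordered(val_ds)

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(train_config.seed)))
    params = init.copy() if init is not None else init_params(model_config, train_config.seed)
    theta = flatten_params(params)
    opt = _Adam(theta.size, train_config.learning_rate)

    n = Xtr.shape[0]
    bs = min(train_config.batch_size, n)
    batch_starts = np.arange(0, n, bs)

    state = TrainState()
    best_params = params.copy()
    log_lines = []
    for epoch in range(1, train_config.max_epochs + 1):
        order = rng.permutation(len(batch_starts))
        epoch_loss = 0.0
        for bi, k in enumerate(order):
            s = batch_starts[k]
            sl = slice(s, min(s + bs, n))
            loss, grads = forward_backward(
                Xtr[sl], ytr[sl], params, model_config,
                mode="train", rng=rng, segments=seg_tr[sl],
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {bi} "
                    f"(lr={train_config.learning_rate})"
                )
            epoch_loss += loss * (sl.stop - sl.start)
            theta = opt.step(theta, flatten_params(grads))
            params = unflatten_params(theta, params)
        epoch_loss /= n
        val_loss = _val_loss(params, model_config, Xva, yva, seg_va)
        state.train_history.append(epoch_loss)
        improved = val_loss < state.best_val_loss - train_config.min_delta
        early_stopping_update(state, val_loss, train_config.patience, train_config.min_delta)
        if improved:
            best_params = params.copy()
        log_lines.append(json.dumps(
            {"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss,
             "lr": train_config.learning_rate}
        ))
        if state.stopped_early:
            logger.info("early stop at epoch %d (best epoch %d)", epoch, state.best_epoch)
            break

    if train_config.log_path:
        Path(train_config.log_path).parent.mkdir(parents=True, exist_ok=True)
        Path(train_config.log_path).write_text("\n".join(log_lines) + "\n")
    if train_config.checkpoint_path:
        save_checkpoint(
            train_config.checkpoint_path, best_params, model_config,
            scalers=train_ds.scalers, seed=train_config.seed,
        )
    return best_params, state


# --------------------------------------------------------------------------
# Grid search
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Candidate hyperparameter values for the tuning grid.

    Defaults span layers 3–6, hidden sizes 64–256 (powers of two), learning
    rates 1e-4–1e-2, dropout 0.1–0.4 and batches 32–128: 432 combinations.
    """

    n_layers: tuple[int, ...] = (3, 4, 5, 6)
    hidden_size: tuple[int, ...] = (64, 128, 256)
    learning_rate: tuple[float, ...] = (0.0001, 0.001, 0.01)
    dropout_rate: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    batch_size: tuple[int, ...] = (32, 64, 128)

    def combinations(self) -> list[dict]:
        for name in self.__dataclass_fields__:
            if not getattr(self, name):
                raise ValueError(f"GridSpec.{name} must be non-empty")
        keys = ["n_layers", "hidden_size", "learning_rate", "dropout_rate", "batch_size"]
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(getattr(self, k) for k in keys))
        ]


def grid_search(
    grid: GridSpec,
    train_ds: WindowedDataset,
    val_ds: WindowedDataset,
    base_model: ModelConfig,
    base_train: TrainConfig = TrainConfig(),
    subset: int | None = None,
    seed: int = 0,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Train one model per grid combination and rank by validation loss.

    ``subset`` draws that many combinations at random (seeded) for desk-scale
    runs; the full default grid has 432 entries. Ties break toward fewer
    parameters, then earlier enumeration order. A combination whose fit fails
    is recorded with its error and skipped, never fatal.
    """
    combos = grid.combinations()
    enum_order = {i: i for i in range(len(combos))}
    if subset is not None and subset < len(combos):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
        chosen = sorted(rng.choice(len(combos), size=subset, replace=False))
        combos = [combos[i] for i in chosen]
        enum_order = {j: chosen[j] for j in range(len(combos))}

    rows = []
    for j, combo in enumerate(combos):
        mc = replace(
            base_model,
            n_layers=combo["n_layers"],
            hidden_size=combo["hidden_size"],
            dropout_rate=combo["dropout_rate"],
        )
        tc = replace(
            base_train,
            learning_rate=combo["learning_rate"],
            batch_size=combo["batch_size"],
            checkpoint_path=None,
            log_path=None,
        )
        row = dict(combo)
        row["order"] = enum_order[j]
        try:
            params, state = train(train_ds, val_ds, mc, tc)
            row["val_loss"] = state.best_val_loss
            row["n_parameters"] = params.n_parameters()
            row["status"] = "ok"
        except Exception as exc:  # a single failed fit must not kill the sweep
            logger.warning("grid combination %s failed: %s", combo, exc)
            row["val_loss"] = math.nan
            row["n_parameters"] = math.nan
            row["status"] = f"failed: {exc}"
        rows.append(row)

    leaderboard = pd.DataFrame(rows)
    ok = leaderboard[leaderboard["status"] == "ok"]
    if ok.empty:
        raise RuntimeError("every grid combination failed to fit")
    ok = ok.sort_values(["val_loss", "n_parameters", "order"], kind="stable")
    best = ok.iloc[0]
    best_config = replace(
        base_model,
        n_layers=int(best["n_layers"]),
        hidden_size=int(best["hidden_size"]),
        dropout_rate=float(best["dropout_rate"]),
    )
    leaderboard = leaderboard.sort_values(
        ["val_loss", "n_parameters", "order"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    return best_config, leaderboard
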