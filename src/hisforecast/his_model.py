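"""Attention-augmented stacked-LSTM regressor for daily HIS forecasting.

The model reads a window X = {x_1, …, x_T} of normalized daily feature
vectors through a stack of L LSTM layers,

    h_t = LSTM(x_t, h_{t-1}, c_{t-1}),

scores each top-layer state against the final state h_T through a bilinear
attention form,

    alpha_t = softmax_t( h_t^T  W_a  h_T ),

collapses the sequence into a context vector c = sum_t alpha_t h_t, and maps
it through a dense head y_hat = sigma(W c + b). Training minimizes a
composite objective: mean squared error plus a temporal-smoothness penalty,

    L = MSE(y, y_hat) + lambda * mean_t (y_hat_t - y_hat_{t+1})^2,

which damps abrupt jumps between consecutive predictions. With a one-day
horizon the consecutive predictions are those of time-adjacent windows of the
same participant inside a batch (batches are built time-ordered per
participant so the pairing is well defined).

Regularization follows recurrent-network practice: DropConnect randomly
zeroes individual recurrent weights during training (with inverse-probability
rescaling), and ordinary Dropout is applied to the hidden sequences passed
between stacked layers. Evaluation mode is exactly deterministic.

Everything — forward pass, analytic backward pass, parameter initialization —
is plain float64 numpy; the backward pass is validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "ModelConfig",
    "ModelParams",
    "EncoderState",
    "AttentionProfile",
    "Prediction",
    "init_params",
    "lstm_stack_forward",
    "attention_weights",
    "context_vector",
    "output_head",
    "apply_dropconnect",
    "composite_loss",
    "composite_loss_segmented",
    "predict",
    "forward_backward",
    "flatten_params",
    "unflatten_params",
    "save_checkpoint",
    "load_checkpoint",
]


# --------------------------------------------------------------------------
# Configuration and parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Architecture and regularization hyperparameters.

    Defaults are the grid-search-selected operating point: five stacked LSTM
    layers of 128 hidden units with dropout/DropConnect rates of 0.2 and a
    smoothness weight of 0.1. ``attention=False`` replaces the attention
    pooling by "take h_T", the plain-LSTM ablation used as a baseline.
    """

    n_channels: int
    n_layers: int = 5
    hidden_size: int = 128
    dropout_rate: float = 0.2
    dropconnect_rate: float = 0.2
    smoothness_weight: float = 0.1
    output_activation: Literal["identity", "scaled_sigmoid"] = "identity"
    window: int = 7
    horizon: int = 1
    attention: bool = True

    def validate(self) -> None:
        if self.n_layers < 1:
            raise ValueError(f"n_layers must be >= 1, got {self.n_layers}")
        for name in ("dropout_rate", "dropconnect_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {r}")
        if self.smoothness_weight < 0:
            raise ValueError(f"smoothness_weight must be >= 0, got {self.smoothness_weight}")
        if self.hidden_size < 1 or self.n_channels < 1:
            raise ValueError("hidden_size and n_channels must be >= 1")


@dataclass
class LayerParams:
    """One LSTM layer's weights; gate row-blocks ordered (i, f, g, o)."""

    W_x: np.ndarray  # (4*hidden, in_dim)
    W_h: np.ndarray  # (4*hidden, hidden)
    b: np.ndarray    # (4*hidden,)


@dataclass
class ModelParams:
    """All learnable arrays: LSTM stack, attention matrix, dense head."""

    layers: list[LayerParams]
    W_a: np.ndarray    # (hidden, hidden)
    W_out: np.ndarray  # (horizon, hidden)
    b_out: np.ndarray  # (horizon,)

    def copy(self) -> "ModelParams":
        return ModelParams(
            layers=[LayerParams(l.W_x.copy(), l.W_h.copy(), l.b.copy()) for l in self.layers],
            W_a=self.W_a.copy(),
            W_out=self.W_out.copy(),
            b_out=self.b_out.copy(),
        )

    def n_parameters(self) -> int:
        n = self.W_a.size + self.W_out.size + self.b_out.size
        for l in self.layers:
            n += l.W_x.size + l.W_h.size + l.b.size
        return n

    def check_finite(self) -> None:
        for arr in _iter_arrays(self):
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError("non-finite model parameter encountered")


@dataclass
class EncoderState:
    """Hidden/cell states per layer and time step.

    ``h`` and ``c`` have shape (n_layers, T, hidden); ``top`` is the
    top-layer hidden sequence (T, hidden) the attention reads.
    """

    h: np.ndarray
    c: np.ndarray

    @property
    def top(self) -> np.ndarray:
        return self.h[-1]


@dataclass
class AttentionProfile:
    """Per-window attention weights and the pooled context vector."""

    alpha: np.ndarray    # (T,) or (B, T); sums to 1 along the last axis
    context: np.ndarray  # (hidden,) or (B, hidden)


@dataclass
class Prediction:
    """Model output on the normalized [0, 1] HIS scale plus attention."""

    y: np.ndarray  # (H,) or (B, H)
    attention: AttentionProfile


def _iter_arrays(params: ModelParams):
    for l in params.layers:
        yield l.W_x
        yield l.W_h
        yield l.b
    yield params.W_a
    yield params.W_out
    yield params.b_out


def flatten_params(params: ModelParams) -> np.ndarray:
    """Concatenate all parameter arrays into one float64 vector."""
    return np.concatenate([a.ravel() for a in _iter_arrays(params)])


def unflatten_params(vec: np.ndarray, template: ModelParams) -> ModelParams:
    """Rebuild a ModelParams with the template's shapes from a flat vector."""
    out = template.copy()
    i = 0
    for a in _iter_arrays(out):
        a[...] = vec[i : i + a.size].reshape(a.shape)
        i += a.size
    if i != vec.size:
        raise ValueError(f"flat vector has {vec.size} entries, expected {i}")
    return out


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


def init_params(config: ModelConfig, seed: int = 0) -> ModelParams:
    """Seeded initialization: orthogonal recurrent blocks, uniform fan-in
    input weights, forget-gate bias 1.0 (standard LSTM practice). The
    bilinear attention matrix starts at the identity so initial scores are
    plain similarity-to-query; training then reshapes the form."""
    config.validate()
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    H = config.hidden_size
    layers = []
    for l in range(config.n_layers):
        in_dim = config.n_channels if l == 0 else H
        bound = 1.0 / np.sqrt(in_dim)
        W_x = rng.uniform(-bound, bound, size=(4 * H, in_dim))
        W_h = np.concatenate([_orthogonal(rng, H) for _ in range(4)], axis=0)
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget gate
        layers.append(LayerParams(W_x, W_h, b))
    W_a = np.eye(H)
    W_out = rng.uniform(-1.0 / np.sqrt(H), 1.0 / np.sqrt(H), size=(config.horizon, H))
    b_out = np.zeros(config.horizon)
    return ModelParams(layers=layers, W_a=W_a, W_out=W_out, b_out=b_out)


# --------------------------------------------------------------------------
# Regularization masks
# --------------------------------------------------------------------------

def apply_dropconnect(
    weights: np.ndarray,
    rate: float,
    rng: np.random.Generator | None = None,
    mode: Literal["train", "eval"] = "train",
) -> np.ndarray:
    """DropConnect: zero individual weights with probability ``rate``.

    Surviving weights are rescaled by 1/(1−rate) so the expected pre-
    activation is unchanged; eval mode (or rate 0) is the identity.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if mode == "eval" or rate == 0.0:
        return weights
    if rng is None:
        raise ValueError("train-mode DropConnect needs an rng")
    keep = rng.random(weights.shape) >= rate
    return weights * keep / (1.0 - rate)


def _dropconnect_masks(config: ModelConfig, rng, mode: str) -> list[np.ndarray | None]:
    """One multiplicative mask (incl. rescale) per layer's recurrent matrix."""
    masks: list[np.ndarray | None] = []
    H = config.hidden_size
    for _ in range(config.n_layers):
        if mode == "train" and config.dropconnect_rate > 0:
            keep = rng.random((4 * H, H)) >= config.dropconnect_rate
            masks.append(keep / (1.0 - config.dropconnect_rate))
        else:
            masks.append(None)
    return masks


# --------------------------------------------------------------------------
# Forward pass
# --------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(
    X: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    mode: str,
    rng: np.random.Generator | None,
) -> dict:
    """Batched forward pass; returns a cache sufficient for backprop.

    X has shape (B, T, n_channels). Train mode draws one DropConnect mask per
    layer per call and iid Dropout masks per (sample, time, unit) on the
    hidden sequences passed between layers.
    """
    if X.ndim != 3 or X.shape[1] != config.window or X.shape[2] != config.n_channels:
        raise ValueError(
            f"input shape {X.shape} does not match (batch, T={config.window}, "
            f"n_channels={config.n_channels})"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in model input")
    B, T, _ = X.shape
    Hd = config.hidden_size
    L = config.n_layers
    dc_masks = _dropconnect_masks(config, rng, mode)

    cache: dict = {
        "layers": [], "dc_masks": dc_masks, "drop_masks": [], "X": X, "mode": mode,
    }
    inp = X
    all_h = np.zeros((L, B, T, Hd))
    all_c = np.zeros((L, B, T, Hd))
    for l, lp in enumerate(params.layers):
        Wh_eff = lp.W_h if dc_masks[l] is None else lp.W_h * dc_masks[l]
        h_prev = np.zeros((B, Hd))
        c_prev = np.zeros((B, Hd))
        gates = np.zeros((B, T, 4 * Hd))
        hs = np.zeros((B, T, Hd))
        cs = np.zeros((B, T, Hd))
        tanh_cs = np.zeros((B, T, Hd))
        for t in range(T):
            z = inp[:, t] @ lp.W_x.T + h_prev @ Wh_eff.T + lp.b
            i = _sigmoid(z[:, :Hd])
            f = _sigmoid(z[:, Hd : 2 * Hd])
            g = np.tanh(z[:, 2 * Hd : 3 * Hd])
            o = _sigmoid(z[:, 3 * Hd :])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[:, t] = np.concatenate([i, f, g, o], axis=1)
            hs[:, t], cs[:, t], tanh_cs[:, t] = h, c, tc
            h_prev, c_prev = h, c
        cache["layers"].append(
            {"inp": inp, "gates": gates, "h": hs, "c": cs, "tanh_c": tanh_cs, "Wh_eff": Wh_eff}
        )
        all_h[l], all_c[l] = hs, cs
        if l < L - 1:
            if mode == "train" and config.dropout_rate > 0:
                keep = (rng.random(hs.shape) >= config.dropout_rate) / (1.0 - config.dropout_rate)
            else:
                keep = None
            cache["drop_masks"].append(keep)
            inp = hs if keep is None else hs * keep

    Hseq = cache["layers"][-1]["h"]  # (B, T, Hd)
    q = Hseq[:, -1]                  # (B, Hd)
    if config.attention:
        v = q @ params.W_a.T                              # W_a h_T, (B, Hd)
        e = np.einsum("bth,bh->bt", Hseq, v)              # bilinear logits
        e = e - e.max(axis=1, keepdims=True)              # overflow safety
        a = np.exp(e)
        alpha = a / a.sum(axis=1, keepdims=True)
        ctx = np.einsum("bt,bth->bh", alpha, Hseq)
        cache.update(v=v, alpha=alpha)
    else:
        alpha = np.zeros((B, T))
        alpha[:, -1] = 1.0
        ctx = q
        cache.update(v=None, alpha=alpha)

    u = ctx @ params.W_out.T + params.b_out
    if config.output_activation == "scaled_sigmoid":
        y = _sigmoid(u)
    else:
        y = u
    cache.update(Hseq=Hseq, ctx=ctx, u=u, y=y, all_h=all_h, all_c=all_c)
    return cache


# --------------------------------------------------------------------------
# Public forward-pass operations
# --------------------------------------------------------------------------

def lstm_stack_forward(
    window: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    mode: Literal["train", "eval"] = "eval",
    seed: int | None = None,
) -> EncoderState:
    """Run one (T, n_channels) window through the LSTM stack.

    States are initialized to zero. Train mode applies DropConnect to the
    recurrent matrices and Dropout between layers (seeded); eval mode is
    deterministic.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError(f"expected a (T, n_channels) window, got shape {window.shape}")
    rng = None
    if mode == "train":
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed or 0)))
    cache = _forward(window[None], params, config, mode, rng)
    return EncoderState(h=cache["all_h"][:, 0], c=cache["all_c"][:, 0])


def attention_weights(H: np.ndarray, W_a: np.ndarray) -> np.ndarray:
    """Softmax over t of the bilinear scores h_t^T W_a h_T.

    The query is the final top-layer state h_T (the last row of ``H``); the
    normalization runs over all T steps including the query step itself.
    Computed with max-subtraction so large logits cannot overflow.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError(f"expected (T, hidden) states with T >= 1, got {H.shape}")
    if not np.all(np.isfinite(H)) or not np.all(np.isfinite(W_a)):
        raise ValueError("non-finite states or attention matrix")
    e = H @ (W_a @ H[-1])
    e = e - e.max()
    a = np.exp(e)
    return a / a.sum()


def context_vector(H: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Convex combination c = sum_t alpha_t h_t of the top-layer states."""
    H = np.asarray(H, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if H.shape[0] != alpha.shape[0]:
        raise ValueError(f"length mismatch: {H.shape[0]} states vs {alpha.shape[0]} weights")
    return alpha @ H


def output_head(
    c: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    activation: Literal["identity", "scaled_sigmoid"] = "identity",
) -> np.ndarray:
    """Dense head y_hat = sigma(W c + b).

    ``identity`` is the regression default on normalized targets;
    ``scaled_sigmoid`` squashes onto (0, 1) since targets live there.
    """
    u = np.asarray(W) @ np.asarray(c, dtype=float) + np.asarray(b)
    return _sigmoid(u) if activation == "scaled_sigmoid" else u


def predict(
    windows: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
) -> Prediction:
    """Deterministic eval-mode forward pass with attention profile.

    Accepts one (T, C) window or a (B, T, C) batch; predictions are on the
    normalized [0, 1] HIS scale.
    """
    windows = np.asarray(windows, dtype=float)
    single = windows.ndim == 2
    X = windows[None] if single else windows
    cache = _forward(X, params, config, "eval", None)
    y, alpha, ctx = cache["y"], cache["alpha"], cache["ctx"]
    if single:
        y, alpha, ctx = y[0], alpha[0], ctx[0]
    return Prediction(y=y, attention=AttentionProfile(alpha=alpha, context=ctx))


# --------------------------------------------------------------------------
# Composite loss
# --------------------------------------------------------------------------

def composite_loss(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    lam: float,
    return_grad: bool = False,
):
    """MSE plus lambda-weighted temporal-smoothness penalty.

    Inputs are (N, T') arrays (a 1-D array is one sample). The MSE averages
    over every sample–step entry; the smoothness term averages, over samples,
    the mean squared difference of consecutive predictions along the T' axis,
    and is zero when T' < 2. With ``return_grad`` also returns dL/dy_pred.
    """
    if lam < 0:
        raise ValueError(f"smoothness weight must be >= 0, got {lam}")
    yt = np.atleast_2d(np.asarray(y_true, dtype=float))
    yp = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if yt.shape != yp.shape:
        raise ValueError(f"shape mismatch: y_true {yt.shape} vs y_pred {yp.shape}")
    N, Tp = yp.shape
    err = yp - yt
    mse = float(np.mean(err**2))
    grad = 2.0 * err / err.size
    smooth = 0.0
    if Tp >= 2:
        d = yp[:, :-1] - yp[:, 1:]
        smooth = float(np.mean(np.sum(d**2, axis=1) / (Tp - 1)))
        if return_grad:
            g = 2.0 * d / (N * (Tp - 1))
            grad[:, :-1] += lam * g
            grad[:, 1:] -= lam * g
    loss = mse + lam * smooth
    if return_grad:
        return loss, grad.reshape(np.asarray(y_pred, dtype=float).shape)
    return loss


def composite_loss_segmented(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    lam: float,
    segments: np.ndarray,
    return_grad: bool = False,
):
    """Composite loss for H=1 batches of time-ordered windows.

    ``segments`` labels each window's participant; the smoothness penalty is
    the mean squared difference over consecutive batch rows that belong to
    the same participant (time-adjacent windows), zero when no such pair
    exists. The MSE term is identical to :func:`composite_loss`.
    """
    if lam < 0:
        raise ValueError(f"smoothness weight must be >= 0, got {lam}")
    yt = np.asarray(y_true, dtype=float).reshape(-1)
    yp = np.asarray(y_pred, dtype=float).reshape(-1)
    seg = np.asarray(segments)
    if not (yt.shape == yp.shape == seg.shape):
        raise ValueError("y_true, y_pred and segments must have equal lengths")
    err = yp - yt
    mse = float(np.mean(err**2))
    grad = 2.0 * err / err.size
    pair = seg[:-1] == seg[1:]
    n_pairs = int(pair.sum())
    smooth = 0.0
    if n_pairs > 0:
        d = (yp[:-1] - yp[1:]) * pair
        smooth = float(np.sum(d**2) / n_pairs)
        if return_grad:
            g = 2.0 * d / n_pairs
            grad[:-1] += lam * g
            grad[1:] -= lam * g
    loss = mse + lam * smooth
    if return_grad:
        return loss, grad.reshape(np.asarray(y_pred, dtype=float).shape)
    return loss


# --------------------------------------------------------------------------
# Backward pass
# --------------------------------------------------------------------------

def _backward(dY: np.ndarray, cache: dict, params: ModelParams, config: ModelConfig) -> ModelParams:
    """Analytic gradients of a scalar loss w.r.t. every parameter.

    ``dY`` is dL/dy of shape (B, horizon). Returns a ModelParams-shaped
    gradient container. Mirrors `_forward` exactly, including the sampled
    DropConnect/Dropout masks stored in the cache.
    """
    B, T, _ = cache["X"].shape
    Hd = config.hidden_size
    L = config.n_layers
    grads = ModelParams(
        layers=[
            LayerParams(np.zeros_like(l.W_x), np.zeros_like(l.W_h), np.zeros_like(l.b))
            for l in params.layers
        ],
        W_a=np.zeros_like(params.W_a),
        W_out=np.zeros_like(params.W_out),
        b_out=np.zeros_like(params.b_out),
    )

    if config.output_activation == "scaled_sigmoid":
        y = cache["y"]
        du = dY * y * (1.0 - y)
    else:
        du = dY
    grads.W_out += du.T @ cache["ctx"]
    grads.b_out += du.sum(axis=0)
    dctx = du @ params.W_out  # (B, Hd)

    Hseq = cache["Hseq"]
    dH = np.zeros_like(Hseq)  # (B, T, Hd)
    if config.attention:
        alpha, v = cache["alpha"], cache["v"]
        q = Hseq[:, -1]
        dalpha = np.einsum("bh,bth->bt", dctx, Hseq)
        dH += alpha[:, :, None] * dctx[:, None, :]
        de = alpha * (dalpha - np.sum(alpha * dalpha, axis=1, keepdims=True))
        dv = np.einsum("bt,bth->bh", de, Hseq)
        dH += de[:, :, None] * v[:, None, :]
        grads.W_a += dv.T @ q
        dH[:, -1] += dv @ params.W_a
    else:
        dH[:, -1] += dctx

    # BPTT through the stack, top layer down
    d_out = dH
    for l in range(L - 1, -1, -1):
        lc = cache["layers"][l]
        lp = params.layers[l]
        Wh_eff = lc["Wh_eff"]
        dh_next = np.zeros((B, Hd))
        dc_next = np.zeros((B, Hd))
        d_inp = np.zeros_like(lc["inp"])
        dWx = grads.layers[l].W_x
        dWh_eff = np.zeros_like(lp.W_h)
        db = grads.layers[l].b
        for t in range(T - 1, -1, -1):
            g4 = lc["gates"][:, t]
            i, f = g4[:, :Hd], g4[:, Hd : 2 * Hd]
            g, o = g4[:, 2 * Hd : 3 * Hd], g4[:, 3 * Hd :]
            tc = lc["tanh_c"][:, t]
            c_prev = lc["c"][:, t - 1] if t > 0 else np.zeros((B, Hd))
            h_prev = lc["h"][:, t - 1] if t > 0 else np.zeros((B, Hd))

            dh = d_out[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += dz.T @ lc["inp"][:, t]
            dWh_eff += dz.T @ h_prev
            db += dz.sum(axis=0)
            d_inp[:, t] = dz @ lp.W_x
            dh_next = dz @ Wh_eff
        mask = cache["dc_masks"][l]
        grads.layers[l].W_h += dWh_eff if mask is None else dWh_eff * mask
        if l > 0:
            keep = cache["drop_masks"][l - 1]
            d_out = d_inp if keep is None else d_inp * keep
    return grads


def forward_backward(
    X: np.ndarray,
    y: np.ndarray,
    params: ModelParams,
    config: ModelConfig,
    mode: Literal["train", "eval"] = "train",
    rng: np.random.Generator | None = None,
    segments: np.ndarray | None = None,
) -> tuple[float, ModelParams]:
    """Composite loss and its analytic parameter gradients for one batch.

    With horizon 1 and ``segments`` given, the smoothness penalty couples
    time-adjacent windows of the same participant within the batch;
    otherwise it runs along the horizon axis of each prediction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(X.shape[0], config.horizon)
    cache = _forward(X, params, config, mode, rng)
    lam = config.smoothness_weight
    if segments is not None and config.horizon == 1:
        loss, dY = composite_loss_segmented(y, cache["y"], lam, segments, return_grad=True)
        dY = dY.reshape(-1, 1)
    else:
        loss, dY = composite_loss(y, cache["y"], lam, return_grad=True)
    grads = _backward(dY, cache, params, config)
    return float(loss), grads


# --------------------------------------------------------------------------
# Checkpointing
# --------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(
    path: str | Path,
    params: ModelParams,
    config: ModelConfig,
    scalers: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> None:
    """Serialize (config, params, scalers, seed) to one .npz, plus a JSON
    sidecar with the config for human inspection."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {"W_a": params.W_a, "W_out": params.W_out, "b_out": params.b_out}
    for l, lp in enumerate(params.layers):
        arrays[f"L{l}_W_x"] = lp.W_x
        arrays[f"L{l}_W_h"] = lp.W_h
        arrays[f"L{l}_b"] = lp.b
    meta = {
        "version": _CHECKPOINT_VERSION,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "scalers": {k: list(v) for k, v in (scalers or {}).items()},
        "seed": seed,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path: str | Path):
    """Inverse of :func:`save_checkpoint`.

    Returns (params, config, scalers, seed).
    """
    npz = np.load(Path(path))
    meta = json.loads(bytes(npz["meta_json"]).decode())
    if meta["version"] != _CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    config = ModelConfig(**meta["config"])
    layers = [
        LayerParams(npz[f"L{l}_W_x"], npz[f"L{l}_W_h"], npz[f"L{l}_b"])
        for l in range(config.n_layers)
    ]
    params = ModelParams(
        layers=layers, W_a=npz["W_a"], W_out=npz["W_out"], b_out=npz["b_out"]
    )
    scalers = {k: tuple(v) for k, v in meta["scalers"].items()}
    return params, config, scalers, meta["seed"]


def plain_lstm_config(config: ModelConfig) -> ModelConfig:
    """Attention-ablated configuration: pooling = take h_T, no smoothness."""
    return replace(config, attention=False, smoothness_weight=0.0)
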