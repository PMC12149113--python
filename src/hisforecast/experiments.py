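"""Desk-scale study protocols shared by the test suite and the
reproduction script.

Each function runs one self-contained experiment end to end — generate a
seeded cohort, preprocess, train, measure — at sizes chosen so the whole
battery completes in minutes on one CPU: ranking uses 64-participant
cohorts and a 2-layer/24-unit model, the regularization and attention
studies 32-participant cohorts and 16 units. The statistical structure of
the cohorts (trajectory shape, noise levels, couplings) is the generator's
defaults throughout; only the scale is reduced.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .evaluation import (
    LinearARBaseline,
    ModelPredictor,
    PersistenceBaseline,
    evaluate_model,
)
from .his_model import (
    ModelConfig,
    flatten_params,
    forward_backward,
    init_params,
    plain_lstm_config,
    predict,
    unflatten_params,
)
from .preprocessing import WindowedDataset, prepare
from .synthetic_cohort import SyntheticConfig, generate_cohort, generate_probe_cohort
from .training import TrainConfig, train

__all__ = [
    "gradient_check",
    "memorization_experiment",
    "smoothness_experiment",
    "attention_probe_experiment",
    "ranking_experiment",
]

# shared desk-scale model for the cohort studies
_SMALL_MODEL = dict(n_channels=20, window=7, horizon=1,
                    dropout_rate=0.1, dropconnect_rate=0.1)


def gradient_check(seed: int = 0, step: float = 1e-6) -> float:
    """Max relative error, analytic vs central-difference gradients.

    Uses a deliberately tiny model (1 layer, 3 hidden units, T=4, horizon 2
    so the smoothness term is active) where finite differences are exact to
    ~1e-10; every parameter is perturbed individually.
    """
    cfg = ModelConfig(n_channels=2, n_layers=1, hidden_size=3, window=4, horizon=2,
                      dropout_rate=0.0, dropconnect_rate=0.0, smoothness_weight=0.1)
    params = init_params(cfg, seed=seed)
    rng = np.random.default_rng(seed)
    X = rng.random((3, 4, 2))
    y = rng.random((3, 2))
    _, grads = forward_backward(X, y, params, cfg, mode="eval")
    g = flatten_params(grads)
    theta = flatten_params(params)
    num = np.zeros_like(theta)
    for i in range(theta.size):
        tp = theta.copy(); tp[i] += step
        tm = theta.copy(); tm[i] -= step
        lp, _ = forward_backward(X, y, unflatten_params(tp, params), cfg, mode="eval")
        lm, _ = forward_backward(X, y, unflatten_params(tm, params), cfg, mode="eval")
        num[i] = (lp - lm) / (2 * step)
    rel = np.abs(g - num) / np.maximum(1e-8, np.abs(g) + np.abs(num))
    return float(rel.max())


def memorization_experiment(seed: int = 0, n_windows: int = 8, max_epochs: int = 500) -> float:
    """Final training loss after overfitting a tiny random dataset.

    A healthy optimizer must drive a 2-layer/16-unit model to near-zero
    loss on 8 windows; returns the last epoch's training loss (normalized
    scale, no smoothness term).
    """
    rng = np.random.default_rng(seed)
    T, C = 7, 20
    ds = WindowedDataset(
        inputs=rng.random((n_windows, T, C)),
        targets=rng.random((n_windows, 1)),
        his_history=rng.random((n_windows, T)) * 9 + 1,
        index=[("P0", i) for i in range(n_windows)],
        scalers={}, channel_names=[f"c{i}" for i in range(C)],
    )
    cfg = ModelConfig(n_channels=C, n_layers=2, hidden_size=16, window=T, horizon=1,
                      dropout_rate=0.0, dropconnect_rate=0.0, smoothness_weight=0.0)
    tcfg = TrainConfig(learning_rate=0.01, batch_size=n_windows,
                       max_epochs=max_epochs, patience=max_epochs, seed=seed)
    _, state = train(ds, ds, cfg, tcfg)
    return float(state.train_history[-1])


def _val_roughness(params, cfg, ds: WindowedDataset) -> float:
    """Mean |y_hat_t − y_hat_{t+1}| over time-adjacent same-participant windows."""
    order = sorted(range(ds.n_windows), key=lambda i: ds.index[i])
    y = predict(ds.inputs[order], params, cfg).y.reshape(-1)
    seg = np.array([ds.index[i][0] for i in order])
    pair = seg[:-1] == seg[1:]
    return float(np.abs(y[:-1] - y[1:])[pair].mean())


def smoothness_experiment(
    seed: int,
    lambdas: tuple[float, ...] = (0.0, 0.1, 1.0),
    n_participants: int = 32,
) -> list[float]:
    """Validation roughness of models trained at increasing smoothness weight.

    Returns one roughness value per lambda; a working penalty makes the
    sequence (stochastically) non-increasing.
    """
    records = generate_cohort(SyntheticConfig(n_participants=n_participants, seed=seed))
    datasets, _ = prepare(records, seed=seed)
    out = []
    for lam in lambdas:
        cfg = ModelConfig(n_layers=2, hidden_size=16, smoothness_weight=lam, **_SMALL_MODEL)
        tcfg = TrainConfig(learning_rate=3e-3, batch_size=64, max_epochs=60,
                           patience=10, seed=seed)
        params, _ = train(datasets["train"], datasets["val"], cfg, tcfg)
        out.append(_val_roughness(params, cfg, datasets["val"]))
    return out


def attention_probe_experiment(
    seed: int,
    lag: int = 3,
    n_participants: int = 32,
) -> np.ndarray:
    """Mean test-set attention profile on the planted-signal cohort.

    The cohort's HIS depends only on one channel ``lag`` days back, i.e. on
    relative window position T − lag; returns the (T,) mean attention
    weights of a model trained on it.
    """
    records = generate_probe_cohort(n_participants=n_participants, lag=lag, seed=seed)
    datasets, _ = prepare(records, seed=seed)
    cfg = ModelConfig(n_layers=2, hidden_size=16, smoothness_weight=0.0, **_SMALL_MODEL)
    tcfg = TrainConfig(learning_rate=3e-3, batch_size=64, max_epochs=80,
                       patience=10, seed=seed)
    params, _ = train(datasets["train"], datasets["val"], cfg, tcfg)
    alpha = predict(datasets["test"].inputs, params, cfg).attention.alpha
    return alpha.mean(axis=0)


_METRICS = ("mae", "rmse", "r2", "evs", "mbe")


def ranking_experiment(
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
    n_participants: int = 64,
) -> dict[str, dict[str, list[float]]]:
    """Model-vs-baseline comparison on default-structure cohorts.

    For each seed: generate a cohort, train the full attention model and
    the attention-ablated plain LSTM (identical stack, pooling = take h_T,
    no smoothness), fit persistence and AR(3) baselines, and record each
    model's median per-participant test metrics. Returns
    {model: {metric: [per-seed medians]}} for models ``his_model``,
    ``lstm_plain``, ``persistence``, ``linear_ar``.
    """
    results: dict[str, dict[str, list[float]]] = {
        m: {k: [] for k in _METRICS}
        for m in ("his_model", "lstm_plain", "persistence", "linear_ar")
    }

    def record_medians(name, predictor, ds) -> None:
        per = evaluate_model(predictor, ds)
        for k in _METRICS:
            results[name][k].append(
                float(np.median([m.as_dict()[k] for m in per.values()]))
            )

    for seed in seeds:
        records = generate_cohort(SyntheticConfig(n_participants=n_participants, seed=seed))
        datasets, _ = prepare(records, seed=seed)
        tr, va, te = datasets["train"], datasets["val"], datasets["test"]
        cfg = ModelConfig(n_layers=2, hidden_size=24, smoothness_weight=0.1, **_SMALL_MODEL)
        tcfg = TrainConfig(learning_rate=3e-3, batch_size=64, max_epochs=200,
                           patience=25, seed=seed)
        params, _ = train(tr, va, cfg, tcfg)
        record_medians("his_model", ModelPredictor(params=params, config=cfg), te)
        pcfg = plain_lstm_config(cfg)
        pparams, _ = train(tr, va, pcfg, tcfg)
        record_medians("lstm_plain", ModelPredictor(params=pparams, config=pcfg), te)
        record_medians("persistence", PersistenceBaseline(), te)
        record_medians("linear_ar", LinearARBaseline(order=3).fit(tr), te)
    return results
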