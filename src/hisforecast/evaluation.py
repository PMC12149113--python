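"""Metric suite, per-participant error distributions, baselines, forecasting.

All metrics are computed on the original 1–10 HIS scale with the error
convention e = y_hat − y, so a positive Mean Bias Error means systematic
over-prediction. The comparison protocol evaluates every model on the
identical test windows, groups errors by participant, and summarizes the
per-participant metric distributions by their medians — the population a
boxplot of model errors is drawn over.

History-based baselines (persistence, least-squares AR) read the in-window
HIS series; HIS is not an input channel of the learned model. External
baselines (SVR, ARIMA, SARIMA) are thin adapters over scikit-learn and
statsmodels behind the same fit/predict contract.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd

from .his_model import ModelConfig, ModelParams, predict, plain_lstm_config
from .preprocessing import (
    WindowedDataset,
    denormalize_his,
    normalize_his,
)
from .synthetic_cohort import ParticipantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MetricSet",
    "EvalReport",
    "ForecastTrajectory",
    "compute_metrics",
    "evaluate_model",
    "ModelPredictor",
    "baseline_persistence",
    "PersistenceBaseline",
    "baseline_linear_ar",
    "LinearARBaseline",
    "external_baseline_adapter",
    "compare_models",
    "forecast_beyond",
]


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricSet:
    """MAE, RMSE, R², explained variance and mean bias on one error set."""

    mae: float
    rmse: float
    r2: float
    evs: float
    mbe: float

    def as_dict(self) -> dict[str, float]:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2,
                "evs": self.evs, "mbe": self.mbe}


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricSet:
    """All five regression metrics on the supplied scale.

    MAE = mean|e|, RMSE = sqrt(mean e²), R² = 1 − SS_res/SS_tot,
    EVS = 1 − Var(e)/Var(y), MBE = mean(e) with e = y_hat − y. R² and EVS
    need Var(y) > 0; for constant targets they are NaN with a warning.
    R² and EVS coincide exactly when the mean error is zero.
    """
    y = np.asarray(y_true, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if y.size != p.size:
        raise ValueError(f"length mismatch: {y.size} vs {p.size}")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    e = p - y
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    mbe = float(np.mean(e))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant y_true: R² and EVS are undefined", RuntimeWarning)
        r2 = evs = float("nan")
    else:
        r2 = 1.0 - float(np.sum(e**2)) / ss_tot
        evs = 1.0 - float(np.var(e)) / float(np.var(y))
    return MetricSet(mae=mae, rmse=rmse, r2=r2, evs=evs, mbe=mbe)


# --------------------------------------------------------------------------
# Predictor contract and the learned-model wrapper
# --------------------------------------------------------------------------

class Predictor(Protocol):
    def predict_his(self, ds: WindowedDataset) -> np.ndarray:  # (n_windows, H), 1–10 scale
        ...


@dataclass
class ModelPredictor:
    """Trained HIS model behind the uniform predictor contract."""

    params: ModelParams
    config: ModelConfig

    def predict_his(self, ds: WindowedDataset) -> np.ndarray:
        y = predict(ds.inputs, self.params, self.config).y
        return denormalize_his(y.reshape(ds.n_windows, self.config.horizon))


# --------------------------------------------------------------------------
# Per-participant evaluation
# --------------------------------------------------------------------------

def evaluate_model(
    predictor: Predictor,
    ds: WindowedDataset,
    min_windows: int = 2,
) -> dict[str, MetricSet]:
    """Per-participant metric sets on the test windows (1–10 scale).

    Participants with fewer than ``min_windows`` windows cannot support the
    metric suite and are excluded with a logged note.
    """
    if ds.n_windows == 0:
        raise ValueError("test dataset has no windows")
    preds = np.asarray(predictor.predict_his(ds), dtype=float).reshape(ds.n_windows, -1)
    truths = denormalize_his(ds.targets)
    pids = np.array(ds.participant_ids())
    out: dict[str, MetricSet] = {}
    for pid in sorted(set(pids)):
        sel = pids == pid
        if int(sel.sum()) * truths.shape[1] < min_windows:
            logger.info("participant %s has < %d test windows; excluded", pid, min_windows)
            continue
        out[pid] = compute_metrics(truths[sel], preds[sel])
    return out


def _median_summary(per_participant: dict[str, MetricSet]) -> dict[str, float]:
    if not per_participant:
        return {}
    return {
        k: float(np.median([m.as_dict()[k] for m in per_participant.values()]))
        for k in ("mae", "rmse", "r2", "evs", "mbe")
    }


@dataclass
class EvalReport:
    """Per-model, per-participant metric distributions plus medians."""

    per_model: dict[str, dict[str, MetricSet]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def medians(self) -> dict[str, dict[str, float]]:
        return {m: _median_summary(d) for m, d in self.per_model.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (model, pid, metric, value)
            for model, d in self.per_model.items()
            for pid, ms in d.items()
            for metric, value in ms.as_dict().items()
        ]
        return pd.DataFrame(rows, columns=["model", "participant", "metric", "value"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "medians": self.medians(),
            "per_model": {
                m: {pid: ms.as_dict() for pid, ms in d.items()}
                for m, d in self.per_model.items()
            },
            "skipped": self.skipped,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def compare_models(
    models: dict[str, Predictor],
    test_ds: WindowedDataset,
    metadata: dict | None = None,
) -> EvalReport:
    """Evaluate every model on the identical test windows.

    A model whose predictor raises is recorded under ``skipped`` and the
    comparison continues. The report is invariant to evaluation order.
    """
    report = EvalReport(metadata=metadata or {})
    for name in sorted(models):
        try:
            report.per_model[name] = evaluate_model(models[name], test_ds)
        except Exception as exc:
            logger.warning("model %s failed evaluation: %s", name, exc)
            report.skipped[name] = str(exc)
    return report


# --------------------------------------------------------------------------
# Baselines
# --------------------------------------------------------------------------

@dataclass
class PersistenceBaseline:
    """Predicts the last observed in-window HIS — the sanity floor."""

    def predict_his(self, ds: WindowedDataset) -> np.ndarray:
        last = ds.his_history[:, -1:]
        return np.tile(last, (1, ds.horizon))


def baseline_persistence(ds: WindowedDataset) -> np.ndarray:
    """Persistence predictions for a dataset (1–10 scale)."""
    return PersistenceBaseline().predict_his(ds)


@dataclass
class LinearARBaseline:
    """Least-squares autoregression on the last ``order`` in-window HIS values.

    Ordinary least squares with intercept; order 0 degenerates to the
    training-mean predictor. A singular design falls back to a small ridge
    jitter (logged).
    """

    order: int = 3
    coef: np.ndarray | None = None  # (order + 1,), intercept first

    def fit(self, train_ds: WindowedDataset) -> "LinearARBaseline":
        p = self.order
        y = denormalize_his(train_ds.targets[:, 0])
        X = np.column_stack([np.ones(train_ds.n_windows)] +
                            ([train_ds.his_history[:, -p:]] if p > 0 else []))
        if X.shape[0] < X.shape[1]:
            raise ValueError("not enough windows to solve the normal equations")
        gram = X.T @ X
        try:
            self.coef = np.linalg.solve(gram, X.T @ y)
        except np.linalg.LinAlgError:
            jitter = 1e-8 * np.trace(gram) / gram.shape[0]
            logger.warning("singular AR design; ridge fallback with jitter %.3g", jitter)
            self.coef = np.linalg.solve(gram + jitter * np.eye(gram.shape[0]), X.T @ y)
        return self

    def predict_his(self, ds: WindowedDataset) -> np.ndarray:
        if self.coef is None:
            raise RuntimeError("LinearARBaseline is not fitted")
        p = self.order
        X = np.column_stack([np.ones(ds.n_windows)] +
                            ([ds.his_history[:, -p:]] if p > 0 else []))
        pred = X @ self.coef
        return np.tile(pred[:, None], (1, ds.horizon))


def baseline_linear_ar(train_ds: WindowedDataset, order: int = 3) -> LinearARBaseline:
    """Fit the least-squares AR baseline on training windows."""
    return LinearARBaseline(order=order).fit(train_ds)


# --------------------------------------------------------------------------
# External baseline adapters
# --------------------------------------------------------------------------

def _adapter_persistence(train_ds: WindowedDataset, **_) -> Predictor:
    return PersistenceBaseline()


def _adapter_linear_ar(train_ds: WindowedDataset, order: int = 3, **_) -> Predictor:
    return baseline_linear_ar(train_ds, order=order)


def _adapter_lstm_plain(
    train_ds: WindowedDataset,
    val_ds: WindowedDataset | None = None,
    model_config: ModelConfig | None = None,
    train_config=None,
    **_,
) -> Predictor:
    """Ablation baseline: same stack, attention replaced by "take h_T", λ=0."""
    from .training import TrainConfig, train as _train

    if val_ds is None:
        raise ValueError("lstm_plain adapter needs a validation split")
    if model_config is None:
        model_config = ModelConfig(n_channels=train_ds.inputs.shape[2],
                                   window=train_ds.window, horizon=train_ds.horizon)
    cfg = plain_lstm_config(model_config)
    params, _ = _train(train_ds, val_ds, cfg, train_config or TrainConfig())
    return ModelPredictor(params=params, config=cfg)


@dataclass
class _SVRAdapter:
    models: list  # one SVR per horizon step

    def predict_his(self, ds: WindowedDataset) -> np.ndarray:
        X = ds.inputs.reshape(ds.n_windows, -1)
        return np.column_stack([m.predict(X) for m in self.models])


def _adapter_svr(train_ds: WindowedDataset, **kwargs) -> Predictor:
    from sklearn.svm import SVR

    X = train_ds.inputs.reshape(train_ds.n_windows, -1)
    models = []
    for h in range(train_ds.horizon):
        m = SVR(kernel=kwargs.get("kernel", "rbf"), C=kwargs.get("C", 1.0))
        m.fit(X, denormalize_his(train_ds.targets[:, h]))
        models.append(m)
    return _SVRAdapter(models=models)


@dataclass
class _SarimaxAdapter:
    """Per-participant univariate (S)ARIMA, evaluated one step ahead.

    Classical univariate models need no training split: for each participant
    in the evaluated dataset the series is reconstructed from its windows,
    the model is fitted once, and in-sample one-step-ahead predictions are
    aligned with the window targets.
    """

    order: tuple
    seasonal_order: tuple

    def predict_his(self, ds: WindowedDataset) -> np.ndarray:
        from statsmodels.tsa.statespace.sarimax import SARIMAX

        pids = np.array(ds.participant_ids())
        preds = np.full((ds.n_windows, ds.horizon), np.nan)
        for pid in sorted(set(pids)):
            rows = np.where(pids == pid)[0]
            series, target_days = _reconstruct_series(ds, rows)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = SARIMAX(
                    series, order=self.order, seasonal_order=self.seasonal_order,
                    enforce_stationarity=False, enforce_invertibility=False,
                ).fit(disp=False)
                one_step = res.get_prediction().predicted_mean
            for r, d in zip(rows, target_days):
                for h in range(ds.horizon):
                    preds[r, h] = one_step[min(d + h, len(one_step) - 1)]
        return preds


def _reconstruct_series(ds: WindowedDataset, rows: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Rebuild one participant's daily HIS series from their windows."""
    day_vals: dict[int, float] = {}
    target_days = []
    for r in rows:
        _, s = ds.index[r]
        for k in range(ds.window):
            day_vals[s + k] = ds.his_history[r, k]
        tgt = denormalize_his(ds.targets[r])
        for h in range(ds.horizon):
            day_vals[s + ds.window + h] = float(tgt[h])
        target_days.append(s + ds.window)
    days = sorted(day_vals)
    if days != list(range(days[0], days[-1] + 1)):
        raise ValueError("cannot reconstruct a contiguous HIS series from these windows")
    return np.array([day_vals[d] for d in days]), [d - days[0] for d in target_days]


_ADAPTERS: dict[str, Callable[..., Predictor]] = {
    "persistence": _adapter_persistence,
    "linear_ar": _adapter_linear_ar,
    "lstm_plain": _adapter_lstm_plain,
    "svr": _adapter_svr,
    "arima": lambda train_ds, **kw: _SarimaxAdapter(order=kw.get("order", (1, 1, 1)),
                                                    seasonal_order=(0, 0, 0, 0)),
    "sarima": lambda train_ds, **kw: _SarimaxAdapter(
        order=kw.get("order", (1, 1, 1)),
        seasonal_order=kw.get("seasonal_order", (1, 0, 1, 7)),
    ),
}


def external_baseline_adapter(name: str, train_ds: WindowedDataset, **kwargs) -> Predictor:
    """Fit a registered baseline under the uniform fit/predict contract.

    Unknown names are rejected with the list of registered adapters; a
    backend failure propagates so `compare_models` can record the skip.
    """
    if name not in _ADAPTERS:
        raise ValueError(
            f"unknown baseline '{name}'; registered: {sorted(_ADAPTERS)}"
        )
    return _ADAPTERS[name](train_ds, **kwargs)


# --------------------------------------------------------------------------
# Beyond-horizon forecasting
# --------------------------------------------------------------------------

@dataclass
class ForecastTrajectory:
    """Day-indexed predicted HIS beyond the observed range (1–10 scale)."""

    participant_id: str
    days: np.ndarray       # absolute day indices, first = n_days_observed
    his_pred: np.ndarray
    covariate_policy: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": self.participant_id,
            "day": self.days,
            "his_pred": self.his_pred,
        })


def forecast_beyond(
    params: ModelParams,
    config: ModelConfig,
    record: ParticipantRecord,
    scalers: dict[str, tuple[float, float]],
    n_future_days: int,
    covariate_policy: str = "cycle",
) -> ForecastTrajectory:
    """Iterative rollout of next-day HIS predictions past the observed days.

    Future covariates are unobserved, so they are synthesized per policy:
    ``cycle`` repeats the participant's last T-day normalized covariate block
    cyclically; ``trend`` extrapolates each channel's least-squares linear
    trend over the last T observed days, clipped to the normalized [0, 1]
    range. HIS is not an input channel, so predictions do not feed back.
    Outputs are clipped to the 1–10 scale.
    """
    if n_future_days < 1:
        raise ValueError(f"n_future_days must be >= 1, got {n_future_days}")
    if record.n_days < config.window:
        raise ValueError(
            f"participant {record.participant_id} has {record.n_days} days < T={config.window}"
        )
    if covariate_policy not in ("cycle", "trend"):
        raise ValueError(f"unknown covariate policy '{covariate_policy}'")

    names = record.schema.names
    lo = np.array([scalers[n][0] for n in names])
    hi = np.array([scalers[n][1] for n in names])
    span = np.where(hi > lo, hi - lo, 1.0)
    normed = np.clip((record.channels - lo) / span, 0.0, 1.0)
    normed[:, hi <= lo] = 0.0

    T = config.window
    block = normed[-T:]
    future = np.empty((n_future_days, len(names)))
    if covariate_policy == "cycle":
        for k in range(n_future_days):
            future[k] = block[k % T]
    else:
        t = np.arange(T, dtype=float)
        tbar = t.mean()
        slope = ((t - tbar)[:, None] * (block - block.mean(axis=0))).sum(axis=0) / (
            ((t - tbar) ** 2).sum()
        )
        intercept = block.mean(axis=0) - slope * tbar
        for k in range(n_future_days):
            future[k] = np.clip(intercept + slope * (T + k), 0.0, 1.0)

    extended = np.vstack([normed, future])
    preds = np.empty(n_future_days)
    for k in range(n_future_days):
        win = extended[record.n_days + k - T : record.n_days + k]
        preds[k] = float(predict(win, params, config).y.reshape(-1)[0])
    his_pred = np.clip(denormalize_his(preds), 1.0, 10.0)
    return ForecastTrajectory(
        participant_id=record.participant_id,
        days=np.arange(record.n_days, record.n_days + n_future_days),
        his_pred=his_pred,
        covariate_policy=covariate_policy,
    )
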