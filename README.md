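# hisforecast

Forecasting daily **Health Improvement Scores** (HIS — a 1–10 Likert
self-rating of perceived health) from multi-domain wearable time series:
physiological, activity, sleep and body channels recorded daily over a
month-long training programme. The package is aimed at researchers in
digital health and sports science who want a fully testable, dependency-light
reference implementation of an attention-augmented recurrent forecaster —
plus a seeded synthetic cohort generator, so every stage runs end-to-end
without access to any private dataset.

## The model

A window **X** = {x₁, …, x_T} of T normalized daily feature vectors is read
by a stack of L LSTM layers, h_t = LSTM(x_t, h_{t−1}, c_{t−1}). The
top-layer states are pooled by bilinear attention against the final state,

    α_t = softmax_t(h_tᵀ W_a h_T),    c = Σ_t α_t h_t,

and a dense head produces the forecast ŷ = σ(Wc + b). Training minimizes
MSE plus a temporal-smoothness penalty,

    ℒ = (1/N) Σ (y − ŷ)² + λ · mean_t (ŷ_t − ŷ_{t+1})²,

which damps abrupt jumps between consecutive predictions. DropConnect
regularizes the recurrent weights, Dropout the inter-layer activations;
Adam with patience-based early stopping and best-epoch checkpointing does
the optimization. The α profile is returned with every prediction as an
interpretability output: it shows which days drove the forecast.

The whole model — forward pass, analytic backprop, Adam — is plain float64
numpy, and the backward pass is verified against finite differences in the
test suite.

## Worked example

```python
from hisforecast import (SyntheticConfig, generate_cohort, prepare, ModelConfig,
                         TrainConfig, train, ModelPredictor, compare_models,
                         external_baseline_adapter)

records = generate_cohort(SyntheticConfig(n_participants=64, seed=1))
datasets, _ = prepare(records, seed=1)   # exclude, impute, scale, window, split

cfg = ModelConfig(n_channels=20, n_layers=2, hidden_size=24, window=7, horizon=1,
                  dropout_rate=0.1, dropconnect_rate=0.1, smoothness_weight=0.1)
params, state = train(datasets["train"], datasets["val"], cfg,
                      TrainConfig(learning_rate=3e-3, max_epochs=200, patience=25, seed=1))

models = {
    "his_model": ModelPredictor(params=params, config=cfg),
    "persistence": external_baseline_adapter("persistence", datasets["train"]),
    "linear_ar": external_baseline_adapter("linear_ar", datasets["train"]),
}
report = compare_models(models, datasets["test"])
for name, med in report.medians().items():
    print(f"{name:12s} median MAE {med['mae']:.3f}  RMSE {med['rmse']:.3f}  "
          f"R2 {med['r2']:.3f}  EVS {med['evs']:.3f}  MBE {med['mbe']:+.3f}")
```

prints

```
stopped at epoch 200, best val loss 0.00200 (epoch 185)
his_model    median MAE 0.333  RMSE 0.461  R2 0.740  EVS 0.758  MBE -0.094
linear_ar    median MAE 0.489  RMSE 0.602  R2 0.495  EVS 0.496  MBE -0.014
persistence  median MAE 0.674  RMSE 0.775  R2 0.077  EVS 0.091  MBE -0.090
```

Read: on a 64-participant synthetic cohort the attention-LSTM predicts
next-day HIS with a median per-participant error of about a third of a
Likert point — roughly half the error of the naive carry-forward
(persistence) baseline and well below an autoregression on the HIS history
alone, because the model exploits the activity/physiology channels that
carry tomorrow's signal. The MBE near zero says neither model is
systematically over- or under-predicting.

The same pipeline is scriptable from the shell:

```bash
his-forecast simulate  --out cohort/ --participants 64 --seed 1
his-forecast preprocess --in cohort/ --out data/ --window 7 --horizon 1 --seed 1
his-forecast train     --data data/ --out model/best.npz --seed 1
his-forecast evaluate  --ckpt model/best.npz --data data/ \
                       --baselines persistence,linear_ar --out report/
his-forecast forecast  --ckpt model/best.npz --cohort cohort/ --days 30 --out fc/
```

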