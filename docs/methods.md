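# Methods

## Problem and model

`hisforecast` forecasts a daily self-reported Health Improvement Score
(HIS, a 1–10 Likert rating of perceived health) from multi-domain wearable
time series: physiological (resting/active heart rate, HRV, SpO₂,
respiration rate, body temperature), activity (steps, intensity, distance,
calories, active minutes, posture fractions), sleep (duration, phase
fractions, interruptions) and body (weight, BMI) channels — 20 channels in
all.

A window **X** = {x₁, …, x_T} of T consecutive normalized daily feature
vectors is encoded by a stack of L LSTM layers,

    h_t = LSTM(x_t, h_{t−1}, c_{t−1}),

with layer ℓ > 1 consuming layer ℓ−1's hidden sequence. The top-layer
states are pooled by bilinear attention against the final state h_T,

    α_t = softmax_t(h_tᵀ W_a h_T),     c = Σ_t α_t h_t,

and a dense head maps the context vector to the prediction,
ŷ = σ(Wc + b). Training minimizes a composite objective

    ℒ = (1/N) Σ_i (y_i − ŷ_i)² + λ · (1/(T′−1)) Σ_t (ŷ_t − ŷ_{t+1})²,

mean squared error plus a temporal-smoothness penalty on consecutive
predictions. With a one-day horizon the consecutive predictions are those
of time-adjacent windows of the same participant within a batch; batches
are therefore built time-ordered per participant, and the penalty is
averaged over within-participant adjacent pairs only. The validation loss
used for model selection includes the λ term, so early stopping optimizes
the same objective being trained.

Everything is implemented in float64 numpy — forward pass, analytic
backward pass (validated against central finite differences to < 1e-4
relative error on every parameter) and Adam. Evaluation mode is a pure
function of (input, parameters); bit-identical across calls.

## Defaults and their provenance

| parameter | default | rationale |
|---|---|---|
| LSTM layers L | 5 | selected operating point of the tuning grid (3–6) |
| hidden units | 128 | grid 64–256, powers of two |
| learning rate | 0.001 | Adam, grid {1e-4, 1e-3, 1e-2} |
| dropout / DropConnect rate | 0.2 | grid 0.1–0.4 |
| batch size | 64 | grid {32, 64, 128} |
| early-stopping patience | 10 epochs | monitored on validation loss |
| smoothness weight λ | 0.1 | no stated value exists; exposed as a tunable, and the test battery verifies the *monotone* smoothing effect of λ rather than any fixed value |
| window T | 7 days, stride 1 | weekly windows with daily stride, the common wearable convention; yields 25 windows per 32-day participant |
| horizon H | 1 day | next-day forecasting |
| output activation σ | identity | standard for regression on normalized targets; `scaled_sigmoid` available since targets live in [0, 1] |

Choices the equations leave open, resolved here:

* **Attention query** is h_T itself, and the softmax normalizes over all T
  steps including the query step.
* **W_a initialization**: identity, so initial attention scores are plain
  similarity-to-query; empirically this converges faster than random
  initialization. Recurrent matrices are orthogonal, input weights uniform
  fan-in, forget-gate bias 1.0.
* **DropConnect** masks individual recurrent weights (one mask per layer
  per batch, survivors rescaled by 1/(1−rate)); ordinary Dropout masks the
  hidden sequences passed between stacked layers. Both are identity at
  evaluation.
* **Symbol note**: the cell state c_t and the context vector c are distinct
  objects (`EncoderState.c` vs `AttentionProfile.context`).
* **Scalar-vs-sequence output**: the head emits an H-step vector; the
  default H=1 plus cross-window smoothness satisfies both the scalar-output
  head and the sequential smoothness penalty simultaneously.

## Preprocessing

Participants whose channel matrix has strictly more than 20% missing cells
are excluded (exactly 20% is retained). Remaining gaps are forward-filled;
leading gaps take the channel's first observed value; a channel entirely
missing for a participant is an error. Channels are min–max scaled to
[0, 1] with statistics computed **on the training split only** and applied
(clipped) to validation/test — whether the original statistics were global
or split-wise is unstated, and train-only fitting is the leak-free choice.
The HIS target is mapped to [0, 1] via (HIS − 1)/9 for training; all
reported metrics are computed on the original 1–10 scale after inverse
transform. Splitting is by participant (70/15/15; val/test sizes are
floors, remainder to train), never by window, so overlapping windows of
one person cannot straddle splits. Day indexing is 0-based; a window is
the closed interval [s, s+T−1] with target days [s+T, s+T+H−1].

## Synthetic cohort

The study population (384 participants × 32 days) is private, so the
generator emulates its statistical structure:

* **Latent trajectory**: linear rise (0.12 HIS/day) until day 14, a
  localized Gaussian dip (depth 1.0, width 1 day), then saturating
  logarithmic recovery (rate 0.15, plateau strength 0.15) — the
  rise / slight decline / diminishing-gain rise pattern of training
  adaptation. Day-to-day increments after the dip are provably
  non-increasing.
* **Participants** carry a level offset (sd 0.6) shared between their HIS
  and their channels, plus demographics matched to the study marginals
  (207:177 male:female, mean age 37) that have no effect on the trajectory
  — nothing in the method models demographics.
* **Channels** co-move with latent fitness with realistic signs (resting
  HR falls, steps rise, HRV rises …) and plausible ranges (SpO₂ clipped to
  [85, 100]; sleep-phase fractions sum to 1).
* **Training load**: an iid daily deviation visible in the activity
  channels whose *previous-day* value shifts HIS by 0.3 units — short-range
  structure a channel-reading model can predict but an HIS-history-only
  baseline cannot.
* **HIS** = latent + lagged load + N(0, 0.35²), clipped to [1, 10];
  real-valued by default (it is a regression target), with an option to
  round to integers to mimic Likert reporting. Daily self-report is
  assumed.
* **Missingness** is uniform at random over channel cells (HIS is never
  masked); spike events plant channel anomalies for interpretability
  fixtures and are off by default. A separate probe generator makes HIS
  depend on a single channel at a fixed lag, giving attention a known
  target day.

What the generator does **not** emulate: circadian/sub-daily structure,
device noise models, informative (non-random) missingness, demographic
effect modification, and inter-participant correlation. Tests passing on
these cohorts therefore demonstrate that the machinery is correct and that
the architecture can exploit cross-channel temporal signal — not that the
printed performance numbers of any real cohort are reproduced.

## Evaluation protocol

Metrics: MAE, RMSE, R², explained variance (EVS) and mean bias (MBE), all
on the 1–10 scale with error convention e = ŷ − y. Predictions on the
identical test windows are grouped by participant; each model's
distribution of per-participant metrics is summarized by its median (the
population a boxplot comparison is drawn over). Participants with fewer
than two test windows are excluded from the distribution.

Baselines: persistence (last in-window HIS), least-squares AR(p) on lagged
HIS (from scratch; ridge fallback for singular designs), and adapters over
scikit-learn SVR and statsmodels SARIMAX behind the same fit/predict
contract — a missing or failing backend degrades to a skipped entry. The
in-repo "plain LSTM" ablation is the same stack with pooling replaced by
"take h_T" and λ = 0.

Beyond-horizon forecasting rolls the model forward one day at a time.
Future covariates are synthesized by policy: `cycle` (default) repeats the
last T-day block; `trend` extrapolates each channel's linear trend over
the last T days, clipped to [0, 1]. HIS is not an input channel, so
predictions do not feed back (an autoregressive-HIS mode is intentionally
not the default: the feature set deliberately separates inputs from the
target). Under the cyclic policy the rollout is periodic and its fitted
slope is near zero by construction; upward-trend checks use the trend
policy.

## Desk-scale study sizes

The shipped experiment battery (`hisforecast.experiments`, also driven by
`scripts/acceptance.py`) uses reduced problem sizes chosen as the package's
desk-scale operating point: ranking runs 64-participant cohorts with a
2-layer / 24-unit model (lr 3e-3, ≤200 epochs, patience 25) over 5 seeds;
the smoothness and attention studies use 32-participant cohorts with 16
units; the gradient check uses L=1, hidden 3, T=4. The full-size default
configuration (5×128) trains the same code path, just longer.

## Known limitations and observed behavior

* On the default synthetic cohort the full model clearly outperforms
  persistence and linear-AR baselines, but the attention-ablated plain
  LSTM is a statistical tie (marginally lower median MAE in most seeds).
  This is structural: the synthetic next-day signal concentrates on the
  window's final day, so h_T is already a sufficient statistic and
  attention pooling can only re-weight toward it. Attention's value shows
  where informative days vary — on the lagged-probe cohort the trained
  attention reliably concentrates mass on the planted day.
* The smoothness penalty's effect is monotone but small at λ ≤ 0.1; λ = 1.0
  visibly smooths validation predictions.
* Single-threaded determinism is guaranteed; results are a pure function
  of (config, seed, data).
* Classical SARIMAX adapters fit per participant on the evaluated series
  (one-step-ahead, in-sample), the standard protocol for univariate
  methods that need no training split; they are not re-implementations.
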