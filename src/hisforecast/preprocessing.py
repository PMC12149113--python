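"""Data preparation: exclusion, imputation, normalization, windowing, splits.

The pipeline mirrors standard wearable practice: participants with more than
20% missing channel cells are dropped (strict inequality — exactly 20% is
retained), remaining gaps are forward-filled (with head backfill for leading
gaps), channels are min–max scaled to [0, 1] using statistics from the
training split only, and each participant's series is cut into overlapping
T-day windows whose target is the HIS of the following H days.

The HIS target is mapped to [0, 1] via (HIS − 1) / 9 for training; every
reported metric is computed back on the original 1–10 scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .synthetic_cohort import ParticipantRecord, read_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "WindowedDataset",
    "SplitSpec",
    "exclude_sparse_participants",
    "forward_fill",
    "minmax_normalize",
    "denormalize",
    "make_windows",
    "split_participants",
    "normalize_his",
    "denormalize_his",
    "prepare",
    "save_windowed",
    "load_windowed",
    "window_count",
]

HIS_MIN, HIS_MAX = 1.0, 9.0 + 1.0  # Likert endpoints of the target scale


def normalize_his(his: np.ndarray) -> np.ndarray:
    """Map HIS from the 1–10 Likert scale onto [0, 1]."""
    return (np.asarray(his, dtype=float) - HIS_MIN) / (HIS_MAX - HIS_MIN)


def denormalize_his(y: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize_his`."""
    return np.asarray(y, dtype=float) * (HIS_MAX - HIS_MIN) + HIS_MIN


@dataclass
class WindowedDataset:
    """Overlapping input windows with aligned targets.

    ``inputs`` (n_windows, T, n_channels) hold the normalized channel blocks;
    ``targets`` (n_windows, H) the normalized HIS of the following H days;
    ``his_history`` (n_windows, T) the in-window HIS on the original 1–10
    scale, used only by history-based baselines (HIS is not an input channel).
    ``index`` maps each window back to (participant_id, start_day).
    """

    inputs: np.ndarray
    targets: np.ndarray
    his_history: np.ndarray
    index: list[tuple[str, int]]
    scalers: dict[str, tuple[float, float]]
    channel_names: list[str]
    window: int = 7
    horizon: int = 1

    @property
    def n_windows(self) -> int:
        return self.inputs.shape[0]

    def participant_ids(self) -> list[str]:
        return [pid for pid, _ in self.index]

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            inputs=self.inputs[idx],
            targets=self.targets[idx],
            his_history=self.his_history[idx],
            index=[self.index[i] for i in np.atleast_1d(idx)],
            scalers=self.scalers,
            channel_names=self.channel_names,
            window=self.window,
            horizon=self.horizon,
        )


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint participant-level train/val/test id sets."""

    train: frozenset[str]
    val: frozenset[str]
    test: frozenset[str]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train & self.val or self.train & self.test or self.val & self.test:
            raise ValueError("split sets must be disjoint")


def exclude_sparse_participants(
    records: Sequence[ParticipantRecord], threshold: float = 0.2
) -> tuple[list[ParticipantRecord], list[str]]:
    """Drop records whose missing-cell fraction strictly exceeds ``threshold``.

    Exactly ``threshold`` missing is kept. Returns (kept, excluded ids).
    """
    kept, excluded = [], []
    for rec in records:
        if rec.missing_fraction() > threshold:
            excluded.append(rec.participant_id)
        else:
            kept.append(rec)
    if excluded:
        logger.info("excluded %d participants over %.0f%% missing", len(excluded), threshold * 100)
    return kept, excluded


def forward_fill(record: ParticipantRecord) -> ParticipantRecord:
    """Impute missing channel cells by carrying the last observation forward.

    Leading gaps (no prior observation) take the channel's first observed
    value. A channel with no observation at all for this participant cannot
    be imputed and is rejected.
    """
    rec = record.copy()
    vals, mask = rec.channels, rec.mask
    n_days, n_chan = vals.shape
    for j in range(n_chan):
        col_mask = mask[:, j]
        if col_mask.all():
            name = rec.schema.names[j] if j < len(rec.schema.names) else str(j)
            raise ValueError(
                f"participant {rec.participant_id}: channel '{name}' is entirely "
                "missing and cannot be forward-filled"
            )
        if not col_mask.any():
            continue
        col = vals[:, j]
        obs = np.where(~col_mask)[0]
        # head backfill, then forward fill
        idx = np.maximum.accumulate(np.where(~col_mask, np.arange(n_days), -1))
        idx[idx < 0] = obs[0]
        vals[:, j] = col[idx]
    rec.mask = np.zeros_like(mask)
    return rec


def minmax_normalize(
    records: Sequence[ParticipantRecord],
    scalers: dict[str, tuple[float, float]] | None = None,
) -> tuple[list[ParticipantRecord], dict[str, tuple[float, float]]]:
    """Scale each channel to [0, 1] by min–max.

    When ``scalers`` is None the per-channel min/max are computed from the
    supplied records (call this on the training split only); otherwise the
    given scalers are applied unchanged and the output is clipped to [0, 1].
    Constant channels map to 0.
    """
    if not records:
        return [], dict(scalers or {})
    names = records[0].schema.names
    stacked = np.concatenate([r.channels for r in records], axis=0)
    if np.isnan(stacked).any():
        raise ValueError("minmax_normalize requires fully imputed records")

    fit = scalers is None
    if fit:
        lo = stacked.min(axis=0)
        hi = stacked.max(axis=0)
        scalers = {n: (float(lo[j]), float(hi[j])) for j, n in enumerate(names)}
    else:
        lo = np.array([scalers[n][0] for n in names])
        hi = np.array([scalers[n][1] for n in names])
        degenerate = hi <= lo
        if degenerate.any():
            for j in np.where(degenerate)[0]:
                col = stacked[:, j]
                if col.max() > col.min():
                    raise ValueError(
                        f"scaler for channel '{names[j]}' has min == max but the "
                        "channel is not constant"
                    )

    span = np.where(hi > lo, hi - lo, 1.0)
    out = []
    for rec in records:
        rec = rec.copy()
        scaled = (rec.channels - lo) / span
        scaled[:, hi <= lo] = 0.0
        rec.channels = np.clip(scaled, 0.0, 1.0) if not fit else scaled
        out.append(rec)
    return out, dict(scalers)


def denormalize(
    records: Sequence[ParticipantRecord],
    scalers: dict[str, tuple[float, float]],
) -> list[ParticipantRecord]:
    """Invert :func:`minmax_normalize` (constant channels return their min)."""
    out = []
    for rec in records:
        rec = rec.copy()
        names = rec.schema.names
        lo = np.array([scalers[n][0] for n in names])
        hi = np.array([scalers[n][1] for n in names])
        rec.channels = rec.channels * np.where(hi > lo, hi - lo, 0.0) + lo
        out.append(rec)
    return out


def window_count(n_days: int, window: int, stride: int, horizon: int) -> int:
    """Number of valid window start positions for one participant."""
    last_start = n_days - window - horizon
    if last_start < 0:
        return 0
    return last_start // stride + 1


def make_windows(
    records: Sequence[ParticipantRecord],
    window: int = 7,
    stride: int = 1,
    horizon: int = 1,
) -> WindowedDataset:
    """Cut each participant's series into overlapping (window, target) pairs.

    A window covers days [s, s+T−1] for s = 0, stride, 2·stride, …; its target
    is the HIS of days [s+T, s+T+H−1]. Windows never cross participants.
    Participants too short for a single window contribute none (warned).
    """
    if window < 1 or horizon < 1 or stride < 1:
        raise ValueError("window, stride and horizon must all be >= 1")
    X, y, hist, index = [], [], [], []
    for rec in records:
        if np.isnan(rec.channels).any():
            raise ValueError(f"participant {rec.participant_id} still has missing values")
        k = window_count(rec.n_days, window, stride, horizon)
        if k == 0:
            logger.warning(
                "participant %s has %d days < T+H=%d; no windows",
                rec.participant_id, rec.n_days, window + horizon,
            )
            continue
        for s in range(0, k * stride, stride):
            X.append(rec.channels[s : s + window])
            y.append(normalize_his(rec.his[s + window : s + window + horizon]))
            hist.append(rec.his[s : s + window])
            index.append((rec.participant_id, s))
    names = records[0].schema.names if records else []
    n_chan = len(names)
    return WindowedDataset(
        inputs=np.array(X) if X else np.empty((0, window, n_chan)),
        targets=np.array(y) if y else np.empty((0, horizon)),
        his_history=np.array(hist) if hist else np.empty((0, window)),
        index=index,
        scalers={},
        channel_names=names,
        window=window,
        horizon=horizon,
    )


def split_participants(
    ids: Iterable[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitSpec:
    """Random participant-level partition into train/val/test.

    Val and test sizes are floors of their fractions; the remainder goes to
    train, so no participant is dropped. Splitting by participant (never by
    window) prevents leakage across overlapping windows of the same person.
    """
    ids = sorted(set(ids))
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(ids)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_groups = sum(f > 0 for f in fractions)
    if n < n_groups:
        raise ValueError(f"cannot split {n} participants into {n_groups} non-empty groups")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    perm = rng.permutation(n)
    val = frozenset(ids[i] for i in perm[:n_val])
    test = frozenset(ids[i] for i in perm[n_val : n_val + n_test])
    train = frozenset(ids[i] for i in perm[n_val + n_test :])
    return SplitSpec(train=train, val=val, test=test, seed=seed)


def prepare(
    records: Sequence[ParticipantRecord],
    window: int = 7,
    stride: int = 1,
    horizon: int = 1,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    threshold: float = 0.2,
) -> tuple[dict[str, WindowedDataset], SplitSpec]:
    """Run the full preparation pipeline on raw records.

    Excludes sparse participants, forward-fills, splits by participant,
    fits min–max scalers on the training split only, applies them to all
    splits, and windows each split. Returns ({'train','val','test'}
    datasets, split spec).
    """
    kept, _ = exclude_sparse_participants(records, threshold)
    filled = [forward_fill(r) for r in kept]
    split = split_participants([r.participant_id for r in filled], fractions, seed)
    by_split = {
        "train": [r for r in filled if r.participant_id in split.train],
        "val": [r for r in filled if r.participant_id in split.val],
        "test": [r for r in filled if r.participant_id in split.test],
    }
    norm_train, scalers = minmax_normalize(by_split["train"])
    datasets: dict[str, WindowedDataset] = {}
    for name, recs in by_split.items():
        if name == "train":
            normed = norm_train
        else:
            normed, _ = minmax_normalize(recs, scalers) if recs else ([], scalers)
        ds = make_windows(normed, window=window, stride=stride, horizon=horizon)
        ds.scalers = scalers
        datasets[name] = ds
    return datasets, split


# --------------------------------------------------------------------------
# On-disk bundle (arrays as .npz, index + scalers as JSON sidecar)
# --------------------------------------------------------------------------

def save_windowed(datasets: dict[str, WindowedDataset], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta: dict = {"splits": {}}
    arrays = {}
    for name, ds in datasets.items():
        arrays[f"{name}_inputs"] = ds.inputs
        arrays[f"{name}_targets"] = ds.targets
        arrays[f"{name}_his_history"] = ds.his_history
        meta["splits"][name] = {
            "index": [[pid, int(s)] for pid, s in ds.index],
            "window": ds.window,
            "horizon": ds.horizon,
        }
        meta["scalers"] = {k: list(v) for k, v in ds.scalers.items()}
        meta["channel_names"] = ds.channel_names
    np.savez(outdir / "windows.npz", **arrays)
    (outdir / "windows.json").write_text(json.dumps(meta, indent=1))


def load_windowed(indir: str | Path) -> dict[str, WindowedDataset]:
    indir = Path(indir)
    meta = json.loads((indir / "windows.json").read_text())
    npz = np.load(indir / "windows.npz")
    out = {}
    for name, m in meta["splits"].items():
        out[name] = WindowedDataset(
            inputs=npz[f"{name}_inputs"],
            targets=npz[f"{name}_targets"],
            his_history=npz[f"{name}_his_history"],
            index=[(pid, int(s)) for pid, s in m["index"]],
            scalers={k: tuple(v) for k, v in meta["scalers"].items()},
            channel_names=meta["channel_names"],
            window=int(m["window"]),
            horizon=int(m["horizon"]),
        )
    return out


def load_cohort_dir(indir: str | Path):
    """Convenience: read a simulator output directory into records."""
    return read_cohort(indir)
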