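"""Seeded synthetic wearable cohorts for HIS forecasting.

The study population this package targets — a few hundred participants wearing
consumer devices for about a month, self-reporting a daily Health Improvement
Score (HIS) on a 1–10 Likert scale — is private, so every pipeline stage is
exercised against a generator that emulates its statistical structure instead:

* a shared latent fitness trajectory that rises, dips once, then recovers with
  diminishing gains (the canonical adaptation curve of a training programme);
* twenty daily channels across four domains (physiological, activity, sleep,
  body) whose levels co-move with latent fitness so the signal is learnable;
* a prior-day "training load" deviation, visible through the activity channels,
  that nudges the next day's HIS — the short-range temporal structure an
  attention model should exploit;
* injectable uniform missingness and optional planted channel spikes.

Cohorts are pure functions of their :class:`SyntheticConfig`; the same seed
always yields a bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TrendParams",
    "SyntheticConfig",
    "FeatureSchema",
    "DEFAULT_SCHEMA",
    "ParticipantRecord",
    "latent_his_trajectory",
    "generate_cohort",
    "generate_probe_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
]


# --------------------------------------------------------------------------
# Feature schema
# --------------------------------------------------------------------------

_CHANNEL_DOMAINS: tuple[tuple[str, str], ...] = (
    ("resting_hr", "physiological"),
    ("active_hr", "physiological"),
    ("hrv", "physiological"),
    ("spo2", "physiological"),
    ("respiration_rate", "physiological"),
    ("body_temp", "physiological"),
    ("steps", "activity"),
    ("step_intensity", "activity"),
    ("distance_km", "activity"),
    ("calories_burned", "activity"),
    ("active_minutes", "activity"),
    ("sitting_frac", "activity"),
    ("lying_frac", "activity"),
    ("sleep_hours", "sleep"),
    ("deep_sleep_frac", "sleep"),
    ("light_sleep_frac", "sleep"),
    ("rem_sleep_frac", "sleep"),
    ("sleep_interruptions", "sleep"),
    ("weight_kg", "body"),
    ("bmi", "body"),
)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered channel names grouped by wearable domain.

    Every :class:`ParticipantRecord` column maps to exactly one entry, in
    order. Names are unique by construction.
    """

    channels: tuple[tuple[str, str], ...] = _CHANNEL_DOMAINS

    def __post_init__(self) -> None:
        names = [n for n, _ in self.channels]
        if len(names) != len(set(names)):
            raise ValueError("FeatureSchema channel names must be unique")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.channels]

    @property
    def domains(self) -> list[str]:
        return [d for _, d in self.channels]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def domain_of(self, name: str) -> str:
        return dict(self.channels)[name]

    def __len__(self) -> int:
        return len(self.channels)


DEFAULT_SCHEMA = FeatureSchema()


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrendParams:
    """Parameters of the cohort-level latent HIS trajectory.

    The trajectory rises linearly at ``initial_gain_rate`` (HIS units/day)
    until ``dip_day``, carries a localized Gaussian dip of depth ``dip_depth``
    (HIS units) and width ``dip_width`` (days) centred on ``dip_day``, and
    afterwards recovers with saturating increments: the post-dip gain between
    consecutive days shrinks at a rate controlled by ``plateau_strength``
    (unitless, >= 0; 0 means linear recovery at ``recovery_rate``).
    """

    initial_gain_rate: float = 0.12
    dip_day: int = 14
    dip_depth: float = 1.0
    dip_width: float = 1.0
    recovery_rate: float = 0.15
    plateau_strength: float = 0.15
    baseline: float = 4.0


_DEFAULT_NOISE_SD: dict[str, float] = {
    "resting_hr": 1.5,
    "active_hr": 3.0,
    "hrv": 3.0,
    "spo2": 0.5,
    "respiration_rate": 0.5,
    "body_temp": 0.15,
    "steps": 900.0,
    "step_intensity": 0.05,
    "distance_km": 0.2,
    "calories_burned": 120.0,
    "active_minutes": 8.0,
    "sitting_frac": 0.03,
    "lying_frac": 0.02,
    "sleep_hours": 0.4,
    "deep_sleep_frac": 0.015,
    "light_sleep_frac": 0.02,
    "rem_sleep_frac": 0.015,
    "sleep_interruptions": 0.0,  # Poisson count, no additive noise
    "weight_kg": 0.1,
    "bmi": 0.0,  # derived from weight
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort.

    ``his_noise_sd`` is the sd of the Gaussian reporting noise added to the
    latent trajectory before clipping to [1, 10]. ``load_effect`` scales the
    prior-day training-load deviation's contribution to HIS (HIS units per sd
    of load); the same deviation is injected into the activity channels, so a
    model reading the channels can predict it while an HIS-history-only
    baseline cannot.
    """

    n_participants: int = 384
    n_days: int = 32
    seed: int = 0
    trend: TrendParams = field(default_factory=TrendParams)
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    his_noise_sd: float = 0.35
    participant_sd: float = 0.6
    load_effect: float = 0.3
    missing_rate: float = 0.0
    spike_events: tuple[tuple[int, int, str, float], ...] = ()
    integer_his: bool = False
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ValueError(f"n_participants must be >= 0, got {self.n_participants}")
        if self.n_days < 2:
            raise ValueError(f"n_days must be >= 2, got {self.n_days}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.his_noise_sd < 0:
            raise ValueError(f"his_noise_sd must be >= 0, got {self.his_noise_sd}")
        if self.trend.plateau_strength < 0:
            raise ValueError(
                f"trend.plateau_strength must be >= 0, got {self.trend.plateau_strength}"
            )
        for ev in self.spike_events:
            pid, day, channel, _ = ev
            if not 0 <= day < self.n_days:
                raise ValueError(f"spike_events day out of range: {ev}")
            if channel not in self.schema.names:
                raise ValueError(f"spike_events channel unknown: {ev}")
            if not 0 <= pid < self.n_participants:
                raise ValueError(f"spike_events participant out of range: {ev}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d.pop("schema")
        d["spike_events"] = [list(ev) for ev in self.spike_events]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "trend" in d:
            d["trend"] = TrendParams(**d["trend"])
        if "spike_events" in d:
            d["spike_events"] = tuple(tuple(ev) for ev in d["spike_events"])
        return cls(**d)


# --------------------------------------------------------------------------
# Participant record
# --------------------------------------------------------------------------

@dataclass
class ParticipantRecord:
    """One participant's day-indexed multi-channel series plus HIS target.

    ``channels`` has shape (n_days, n_channels) with columns ordered per the
    schema; missing entries are NaN and flagged True in ``mask``. ``his`` is
    never masked.
    """

    participant_id: str
    sex: str
    age: int
    channels: np.ndarray
    his: np.ndarray
    mask: np.ndarray
    schema: FeatureSchema = field(default_factory=lambda: DEFAULT_SCHEMA)

    @property
    def n_days(self) -> int:
        return self.channels.shape[0]

    def missing_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0

    def copy(self) -> "ParticipantRecord":
        return ParticipantRecord(
            participant_id=self.participant_id,
            sex=self.sex,
            age=self.age,
            channels=self.channels.copy(),
            his=self.his.copy(),
            mask=self.mask.copy(),
            schema=self.schema,
        )


# --------------------------------------------------------------------------
# Latent trajectory
# --------------------------------------------------------------------------

def latent_his_trajectory(
    day: float | np.ndarray,
    trend: TrendParams = TrendParams(),
    n_days: int | None = None,
) -> np.ndarray | float:
    """Cohort-level latent HIS at (possibly fractional) day index ``day``.

    Piecewise-smooth and continuous: linear rise until ``dip_day``, a local
    Gaussian dip, then logarithmic (saturating) recovery whose day-to-day
    increments are strictly non-increasing whenever ``plateau_strength > 0``.
    """
    d = np.asarray(day, dtype=float)
    if np.any(d < 0):
        raise ValueError("day index must be >= 0")
    if n_days is not None and np.any(d >= n_days):
        raise ValueError(f"day index must be < n_days={n_days}")
    t = trend
    rise = t.baseline + t.initial_gain_rate * np.minimum(d, t.dip_day)
    past = np.clip(d - t.dip_day, 0.0, None)
    if t.plateau_strength > 0:
        recovery = (t.recovery_rate / t.plateau_strength) * np.log1p(
            t.plateau_strength * past
        )
    else:
        recovery = t.recovery_rate * past
    dip = t.dip_depth * np.exp(-(((d - t.dip_day) / t.dip_width) ** 2))
    out = rise + recovery - dip
    return float(out) if np.isscalar(day) else out


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def _simulate_participant(
    pid: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> ParticipantRecord:
    schema = config.schema
    days = np.arange(config.n_days, dtype=float)
    base = latent_his_trajectory(days, config.trend)

    sex = "male" if rng.random() < 207 / 384 else "female"
    age = int(np.clip(np.round(rng.normal(37, 9)), 18, 65))
    offset = rng.normal(0.0, config.participant_sd)
    latent = base + offset  # participant's latent fitness in HIS units

    # daily training-load deviation; yesterday's load colours today's HIS
    load = rng.normal(0.0, 1.0, size=config.n_days)
    load_lag = np.concatenate([[0.0], load[:-1]])

    # fitness on a unitless scale for channel couplings
    u = (latent - 4.5) / 2.0
    sd = config.noise_sd
    n = lambda name: rng.normal(0.0, sd.get(name, 0.0), size=config.n_days)

    height = rng.normal(1.70, 0.09)
    weight0 = rng.normal(75.0, 10.0)

    cols: dict[str, np.ndarray] = {}
    cols["resting_hr"] = 68.0 - 5.0 * u + rng.normal(0, 2.0) + n("resting_hr")
    cols["active_hr"] = 128.0 - 6.0 * u + 4.0 * load + rng.normal(0, 4.0) + n("active_hr")
    cols["hrv"] = 48.0 + 10.0 * u + rng.normal(0, 5.0) + n("hrv")
    cols["spo2"] = np.clip(96.5 + 0.8 * u + n("spo2"), 85.0, 100.0)
    cols["respiration_rate"] = 14.5 - 0.8 * u + n("respiration_rate")
    cols["body_temp"] = 36.6 + n("body_temp")
    cols["steps"] = np.clip(
        7000.0 + 2500.0 * u + 1800.0 * load + rng.normal(0, 800.0) + n("steps"), 0, None
    )
    cols["step_intensity"] = np.clip(
        0.45 + 0.08 * u + 0.06 * load + n("step_intensity"), 0.0, 1.0
    )
    cols["distance_km"] = np.clip(cols["steps"] * 0.00075 + n("distance_km"), 0, None)
    cols["calories_burned"] = 2000.0 + 300.0 * u + 150.0 * load + n("calories_burned")
    cols["active_minutes"] = np.clip(45.0 + 15.0 * u + 12.0 * load + n("active_minutes"), 0, None)
    cols["sitting_frac"] = np.clip(0.45 - 0.05 * u + n("sitting_frac"), 0.0, 1.0)
    cols["lying_frac"] = np.clip(0.33 - 0.01 * u + n("lying_frac"), 0.0, 1.0)
    cols["sleep_hours"] = np.clip(7.0 + 0.4 * u + n("sleep_hours"), 3.0, 12.0)

    deep = np.clip(0.20 + 0.03 * u + n("deep_sleep_frac"), 0.02, None)
    light = np.clip(0.55 - 0.02 * u + n("light_sleep_frac"), 0.02, None)
    rem = np.clip(0.25 + n("rem_sleep_frac"), 0.02, None)
    total = deep + light + rem
    cols["deep_sleep_frac"] = deep / total
    cols["light_sleep_frac"] = light / total
    cols["rem_sleep_frac"] = rem / total

    cols["sleep_interruptions"] = rng.poisson(np.clip(2.2 - 0.8 * u, 0.1, None)).astype(float)
    cols["weight_kg"] = weight0 - 0.3 * u + n("weight_kg")
    cols["bmi"] = cols["weight_kg"] / height**2

    channels = np.column_stack([cols[name] for name in schema.names])

    his = latent + config.load_effect * load_lag + rng.normal(
        0.0, config.his_noise_sd, size=config.n_days
    )
    his = np.clip(his, 1.0, 10.0)
    if config.integer_his:
        his = np.clip(np.round(his), 1.0, 10.0)

    return ParticipantRecord(
        participant_id=f"P{pid:04d}",
        sex=sex,
        age=age,
        channels=channels,
        his=his,
        mask=np.zeros_like(channels, dtype=bool),
    )


def generate_cohort(config: SyntheticConfig) -> list[ParticipantRecord]:
    """Generate ``config.n_participants`` seeded participant records.

    Deterministic in ``config``: each participant draws from an independent
    stream spawned from the root seed, so the cohort is bit-identical across
    calls and unaffected by generation order.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_participants + 1)
    records = [
        _simulate_participant(pid, config, np.random.Generator(np.random.PCG64(streams[pid])))
        for pid in range(config.n_participants)
    ]

    for pid, day, channel, magnitude in config.spike_events:
        j = config.schema.index(channel)
        records[pid].channels[day, j] += magnitude

    if config.missing_rate > 0:
        miss_seed = int(streams[-1].generate_state(1)[0] % (2**31))
        records = inject_missingness(records, config.missing_rate, miss_seed)
    return records


def generate_probe_cohort(
    n_participants: int = 32,
    n_days: int = 32,
    lag: int = 3,
    effect: float = 1.5,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> list[ParticipantRecord]:
    """Cohort whose HIS is driven by a single channel at a fixed lag.

    An interpretability fixture: ``step_intensity`` carries an iid standard
    signal and ``HIS(d) = 5.5 + effect * signal(d - lag) + noise``, so a
    forecaster predicting day s+T from window [s, s+T-1] should concentrate
    attention on relative position T - lag, the only informative day. All
    other channels are uninformative noise around their baselines.
    """
    if not 1 <= lag:
        raise ValueError("lag must be >= 1")
    cfg = SyntheticConfig(n_participants=n_participants, n_days=n_days, seed=seed)
    root = np.random.SeedSequence([seed, 9173])
    records = []
    schema = cfg.schema
    j_sig = schema.index("step_intensity")
    for pid, ss in enumerate(root.spawn(n_participants)):
        rng = np.random.Generator(np.random.PCG64(ss))
        rec = _simulate_participant(pid, cfg, rng)
        # overwrite every channel with pure baseline noise (no latent signal)
        rec.channels = rng.normal(0.0, 1.0, size=rec.channels.shape)
        signal = rng.normal(0.0, 1.0, size=n_days)
        rec.channels[:, j_sig] = signal
        lagged = np.concatenate([np.zeros(lag), signal[:-lag]])
        rec.his = np.clip(5.5 + effect * lagged + rng.normal(0, noise_sd, n_days), 1, 10)
        rec.mask = np.zeros_like(rec.channels, dtype=bool)
        records.append(rec)
    return records


def inject_missingness(
    records: Sequence[ParticipantRecord],
    missing_rate: float,
    seed: int,
) -> list[ParticipantRecord]:
    """Mask ~``missing_rate`` of channel cells uniformly at random.

    HIS targets are never masked. Returns new records; inputs are untouched.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    out = []
    for rec in records:
        rec = rec.copy()
        if missing_rate > 0:
            hit = rng.random(rec.channels.shape) < missing_rate
            rec.mask |= hit
            rec.channels[rec.mask] = np.nan
        out.append(rec)
    return out


# --------------------------------------------------------------------------
# Tidy CSV I/O
# --------------------------------------------------------------------------

def write_cohort(records: Sequence[ParticipantRecord], outdir: str | Path) -> None:
    """Write a cohort as tidy CSVs.

    ``channels.csv``: participant_id, day, channel, value, missing (long form);
    ``his.csv``: participant_id, day, his; ``participants.csv``: demographics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chan_rows, his_rows, demo_rows = [], [], []
    for rec in records:
        names = rec.schema.names
        for d in range(rec.n_days):
            for j, name in enumerate(names):
                chan_rows.append(
                    (rec.participant_id, d, name,
                     "" if rec.mask[d, j] else rec.channels[d, j],
                     bool(rec.mask[d, j]))
                )
            his_rows.append((rec.participant_id, d, rec.his[d]))
        demo_rows.append((rec.participant_id, rec.sex, rec.age))
    pd.DataFrame(
        chan_rows, columns=["participant_id", "day", "channel", "value", "missing"]
    ).to_csv(outdir / "channels.csv", index=False)
    pd.DataFrame(his_rows, columns=["participant_id", "day", "his"]).to_csv(
        outdir / "his.csv", index=False
    )
    pd.DataFrame(demo_rows, columns=["participant_id", "sex", "age"]).to_csv(
        outdir / "participants.csv", index=False
    )


def read_cohort(indir: str | Path, schema: FeatureSchema = DEFAULT_SCHEMA) -> list[ParticipantRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    chan = pd.read_csv(indir / "channels.csv")
    his = pd.read_csv(indir / "his.csv")
    demo = pd.read_csv(indir / "participants.csv").set_index("participant_id")
    names = schema.names
    records = []
    for pid, g in chan.groupby("participant_id", sort=True):
        n_days = int(g["day"].max()) + 1
        channels = np.full((n_days, len(names)), np.nan)
        mask = np.zeros((n_days, len(names)), dtype=bool)
        jmap = {name: j for j, name in enumerate(names)}
        unknown = set(g["channel"]) - set(jmap)
        if unknown:
            raise ValueError(f"channels not in schema: {sorted(unknown)}")
        dd = g["day"].to_numpy()
        jj = g["channel"].map(jmap).to_numpy()
        vv = pd.to_numeric(g["value"], errors="coerce").to_numpy()
        mm = g["missing"].to_numpy(dtype=bool)
        channels[dd, jj] = vv
        mask[dd, jj] = mm
        channels[mask] = np.nan
        h = his[his["participant_id"] == pid].sort_values("day")["his"].to_numpy()
        records.append(
            ParticipantRecord(
                participant_id=str(pid),
                sex=str(demo.loc[pid, "sex"]),
                age=int(demo.loc[pid, "age"]),
                channels=channels,
                his=h,
                mask=mask,
                schema=schema,
            )
        )
    return records
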