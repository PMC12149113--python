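import numpy as np
import pytest

from hisforecast import (
    FeatureSchema,
    ModelConfig,
    ParticipantRecord,
    SyntheticConfig,
    generate_cohort,
    init_params,
    prepare,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 participants x 32 days, default structure."""
    return generate_cohort(SyntheticConfig(n_participants=12, seed=7))


@pytest.fixture(scope="session")
def tiny_datasets(tiny_cohort):
    datasets, split = prepare(tiny_cohort, seed=7)
    return datasets


@pytest.fixture
def tiny_model():
    cfg = ModelConfig(n_channels=20, n_layers=2, hidden_size=8, window=7, horizon=1,
                      dropout_rate=0.0, dropconnect_rate=0.0, smoothness_weight=0.1)
    return cfg, init_params(cfg, seed=0)


def make_record(values, mask=None, his=None, pid="P0"):
    """Build a small ParticipantRecord with an ad-hoc schema."""
    values = np.asarray(values, dtype=float)
    n_days, n_chan = values.shape
    schema = FeatureSchema(
        channels=tuple((f"ch{j}", "physiological") for j in range(n_chan))
    )
    if mask is None:
        mask = np.isnan(values)
    if his is None:
        his = np.full(n_days, 5.0)
    return ParticipantRecord(
        participant_id=pid, sex="female", age=37,
        channels=values.copy(), his=np.asarray(his, dtype=float),
        mask=np.asarray(mask, dtype=bool), schema=schema,
    )
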