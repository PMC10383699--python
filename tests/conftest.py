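import numpy as np
import pytest

from vbtval import (
    BlackboxErrorModel,
    DropoutModel,
    LoadVelocityParams,
    NoiseModel,
    SessionConfig,
    generate_session,
)


def clean_session_config(seed: int = 7, **overrides) -> SessionConfig:
    """A fully deterministic, artifact-free session: no noise, no dropouts."""
    base = dict(
        ghost_count=0,
        lv_params=LoadVelocityParams(sd=0.0),
        noise=NoiseModel(
            marker_sd=0.0,
            accel_sd=0.0,
            accel_bias_range=0.0,
            wrist_interference_amp=0.0,
            orientation_sd=0.0,
        ),
        dropout=DropoutModel(markers=0, barbell_imu=0, wrist_imu=0, blackbox=0),
        blackbox=BlackboxErrorModel(
            mult_sd=0.0, miscount_probability=0, validity_fail_probability=0
        ),
        seed=seed,
    )
    base.update(overrides)
    return SessionConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_session():
    """30 noiseless repetitions (5 loads x 6 reps) shared across tests."""
    cfg = clean_session_config(
        loads=[45, 55, 65, 75, 85],
        reps_per_load=6,
        include_1rm_attempt=False,
        exhaustion_reps=0,
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def default_session():
    """One session under the full default study conditions."""
    return generate_session(SessionConfig(seed=1))
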