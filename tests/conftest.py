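import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import optopav as op

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def training_config() -> op.TaskConfig:
    return op.TaskConfig()


@pytest.fixture(scope="session")
def omission_config() -> op.TaskConfig:
    return op.TaskConfig.omission()


@pytest.fixture(scope="session")
def truth() -> op.GroundTruth:
    return op.GroundTruth()


@pytest.fixture(scope="session")
def quiet_truth(truth) -> op.GroundTruth:
    """Ground truth with noise and motion disabled (bleaching kept)."""
    return op.noiseless(truth)


@pytest.fixture(scope="session")
def nac_kernel() -> op.KernelParams:
    return op.REGION_PRESETS["NAc_dopamine"]


@pytest.fixture(scope="session")
def omission_session(omission_config, quiet_truth, nac_kernel):
    """One noiseless omission session: (schedule, trace, dff, manifest)."""
    schedule = op.generate_schedule(omission_config, seed=11, session_index=11)
    trace, manifest = op.simulate_traces(schedule, nac_kernel, quiet_truth,
                                         fs=50.0, seed=11)
    dff = op.preprocess(trace)
    return schedule, trace, dff, manifest
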