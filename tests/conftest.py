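import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import penumbra as pn

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated experiment, shared read-only across tests."""
    cfg = pn.SimConfig(seed=1)
    rois, traces, trials, seizures, lfp, gt = pn.simulate(cfg)
    return {
        "config": cfg,
        "rois": rois,
        "traces": traces,
        "trials": trials,
        "seizures": seizures,
        "lfp": lfp,
        "gt": gt,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
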