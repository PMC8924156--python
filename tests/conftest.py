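import numpy as np
import pytest
from hypothesis import settings

import norcircuit as nc

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def long_session():
    """A 300 s default-condition session shared by recovery tests."""
    params = nc.default_control_params(duration=300.0)
    rec, gt = nc.generate_recording(params, "a01", "saline",
                                    rng=np.random.default_rng(7))
    return params, rec, gt


@pytest.fixture(scope="session")
def tracking_session():
    """One generated tracking trace with its ground-truth bouts."""
    params = nc.default_control_params(duration=240.0)
    trace, gt = nc.generate_tracking(params, rng=np.random.default_rng(11))
    return params, trace, gt


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A tiny on-disk cohort (2 animals per group, 40 s sessions)."""
    out = tmp_path_factory.mktemp("cohort")
    pc = nc.default_control_params(duration=40.0)
    pi = nc.default_impaired_params(duration=40.0)
    nc.generate_cohort(pc, pi, n_per_group=2, out_dir=out, seed=5)
    return out
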