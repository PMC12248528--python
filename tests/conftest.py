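import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radsignet import SimConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-scale cohort with the default clinical schema and a mild
    planted radiomic effect; shared across read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(SimConfig(seed=11).scaled(0.05))


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_cohort):
    """The small cohort written out in the CSV layout the loader consumes."""
    from radsignet import write_cohort

    outdir = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, outdir)
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
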