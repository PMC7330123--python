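import numpy as np
import pytest

from enpp.schedule import SignificanceParams, build_schedule
from enpp.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def schedule_5e5():
    return build_schedule(SignificanceParams(p_adj=5e-5), 10_000)


@pytest.fixture(scope="session")
def schedule_1e7():
    return build_schedule(SignificanceParams(p_adj=1e-7), 10_000)


@pytest.fixture(scope="session")
def small_null_bundle():
    """200 null features, gaussian phenotype, 3 covariates; fast to permute."""
    return generate_dataset(
        SynthConfig(N=80, J=200, phenotype_family="gaussian", seed=42)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
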