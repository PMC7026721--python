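import numpy as np
import pytest

from angioquant import SynthParams, analyze_cohort, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized cohort (31 tumors, 17 controls), fixed seed."""
    return generate_cohort(SynthParams(seed=1))


@pytest.fixture(scope="session")
def default_per_image(default_cohort):
    per_image, assignments = analyze_cohort(default_cohort)
    return per_image, assignments


@pytest.fixture(scope="session")
def small_params():
    """A fast, small cohort configuration for unit tests."""
    return SynthParams(
        n_tumor=4, n_control=3, vessels_per_image=(10, 14), seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
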