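import numpy as np
import pytest

from tpmslat import design_space, mech_response, run_pipeline


@pytest.fixture(scope="session")
def default_space():
    return design_space.DesignSpaceConfig()


@pytest.fixture(scope="session")
def filtered_designs(default_space):
    designs = design_space.enumerate_full_factorial(default_space)
    return design_space.filter_aspect_ratio(designs,
                                            default_space.max_aspect_ratio)


@pytest.fixture(scope="session")
def synthetic_dataset(filtered_designs):
    cfg = mech_response.ResponseGenConfig(seed=0, noise_cv=0.02)
    return mech_response.build_synthetic_dataset(filtered_designs, cfg)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full end-to-end run shared by the surrogate/optimization checks."""
    return run_pipeline(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
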