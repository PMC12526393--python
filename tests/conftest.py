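import pytest

from beechbiomass import GenerativeParams, generate_sample_trees


@pytest.fixture(scope="session")
def default_params() -> GenerativeParams:
    return GenerativeParams(seed=12345)


@pytest.fixture(scope="session")
def trees500(default_params):
    """One moderately large heteroscedastic sample-tree table."""
    return generate_sample_trees(default_params, 500)


@pytest.fixture(scope="session")
def noisefree_params() -> GenerativeParams:
    return GenerativeParams(alpha_var=0.0, seed=7)


@pytest.fixture(scope="session")
def noisefree_trees(noisefree_params):
    return generate_sample_trees(noisefree_params, 120)
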