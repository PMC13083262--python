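import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: the Illumina small-RNA 3' adapter used throughout the tests
ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@pytest.fixture(scope="session")
def adapter() -> str:
    return ADAPTER


@pytest.fixture(scope="session")
def small_dict():
    from tdmdquant import simulate

    return simulate.make_mirna_dictionary(20, 0.0, seed=1)


@pytest.fixture(scope="session")
def small_truth(small_dict):
    from tdmdquant import simulate

    return simulate.make_simulation_truth(small_dict, seed=2, base_range=(20, 200))


@pytest.fixture(scope="session")
def small_table(small_dict, small_truth):
    from tdmdquant import simulate

    return simulate.simulate_isoform_counts(small_dict, small_truth)


@pytest.fixture(autouse=True)
def _no_passenger_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
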