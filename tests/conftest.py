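import pytest

from sofa_oxi import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small generated cohort shared across tests (n=2000, fixed seed)."""
    return generate_cohort(default_config(n=2000, seed=42))


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (n=15000, calibrated defaults)."""
    return generate_cohort(default_config())
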