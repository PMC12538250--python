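import numpy as np
import pytest

from hpburden import REFERENCE_PARAMS, propagate_cohort
from hpburden.synthetic_data import SyntheticConfig, simulate_schedule


@pytest.fixture(scope="session")
def ref_params():
    """Reference HP parameter set (cardiovascular cohort, ages 45-86)."""
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def noise_free_quarterly():
    """Noise-free quarterly schedule on 45-86 generated from the reference curve."""
    return simulate_schedule(SyntheticConfig(noise_free=True))


@pytest.fixture(scope="session")
def ref_trajectory(ref_params):
    """Reference cohort: l0=160,000 diagnosed at 45, quarterly replication mode."""
    return propagate_cohort(ref_params, 45.0, 86.0, step=0.25, l0=160_000.0, mode="replication")


@pytest.fixture(autouse=True)
def _silence_clamp_warnings():
    """HP clamp warnings are expected during optimizer excursions."""
    import warnings

    from hpburden.hp_mortality import ClampWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClampWarning)
        yield
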