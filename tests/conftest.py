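import numpy as np
import pytest
from hypothesis import settings

from shellprov import IsotopeProfile, IsotopeSample

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_profile(
    d18o,
    d13c=None,
    shell_id="S1",
    site="siteX",
    unit="1",
    role="seasonality",
):
    """Build a profile from raw value lists (δ13C defaults to zeros-ish)."""
    if d13c is None:
        d13c = [0.5 + 0.01 * i for i in range(len(d18o))]
    samples = tuple(
        IsotopeSample(index=i, d13c=float(c), d18o=float(o))
        for i, (c, o) in enumerate(zip(d13c, d18o))
    )
    return IsotopeProfile(
        shell_id=shell_id, site=site, unit=unit, samples=samples, role=role
    )


@pytest.fixture
def profile_factory():
    return make_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
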