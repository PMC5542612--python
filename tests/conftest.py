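import pytest

from areadep.index import build_imd
from areadep.synthetic import SyntheticConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A 1,200-area synthetic bundle shared by unit tests."""
    return generate_bundle(SyntheticConfig(n_areas=1200, seed=7))


@pytest.fixture(scope="session")
def small_imd(small_bundle):
    """The index built on the small bundle (published-weight profile)."""
    result, intermediates = build_imd(
        small_bundle.areas,
        small_bundle.indicator_numerators,
        facilities=small_bundle.facilities,
        reference_rates=small_bundle.reference_rates,
    )
    return result, intermediates
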