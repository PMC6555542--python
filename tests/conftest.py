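import numpy as np
import pytest

from archaid.demography import DemographyScenario, simulate_region
from archaid.features import HaplotypeWindow


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def random_window(rng, n=8, n_ref=6, n_sites=20, span=50_000, focal=0):
    """A random toy haplotype window with sorted distinct positions."""
    positions = np.sort(rng.choice(span, size=n_sites, replace=False))
    target = rng.integers(0, 2, size=(n, n_sites)).astype(np.uint8)
    reference = rng.integers(0, 2, size=(n_ref, n_sites)).astype(np.uint8)
    return HaplotypeWindow(
        positions=positions, target=target, reference=reference, start=0, end=span, focal=focal
    )


@pytest.fixture
def toy_window_factory(rng):
    def factory(**kwargs):
        return random_window(rng, **kwargs)

    return factory


@pytest.fixture(scope="session")
def admixed_region():
    """One 50 kb replicate with a strong pulse so archaic tracts are common."""
    scenario = DemographyScenario(m=0.15)
    return simulate_region(scenario, n_target=30, n_ref=30, seed=424242)
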