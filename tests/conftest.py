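import numpy as np
import pytest

from pnvgap.rasterstack_io import GridSpec
from pnvgap.synthetic_landscape import LandscapeConfig, generate
from pnvgap.protection_coverage import resolve_overlaps


@pytest.fixture(scope="session")
def default_landscape():
    """One standard landscape at default study conditions, shared read-only."""
    return generate(LandscapeConfig(seed=7))


@pytest.fixture(scope="session")
def default_protection(default_landscape):
    return resolve_overlaps(default_landscape.pas, default_landscape.grid)


@pytest.fixture(scope="session")
def small_landscape():
    """A 50x50 landscape for the more expensive per-test pipelines."""
    return generate(LandscapeConfig(seed=11, grid=GridSpec(50, 50), n_pa=20, n_towns=4))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
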