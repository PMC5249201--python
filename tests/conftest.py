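import numpy as np
import pytest

from pulmotile.synthetic_data import SectionParams, simulate_section


def small_params(**kw) -> SectionParams:
    """Desk-scale section params for fast unit tests (0.4 x 0.4 mm)."""
    defaults = dict(width_um=400.0, height_um=400.0, n_vessels=1, seed=11,
                    lesion_radius_um=30.0, lesion_radius_sigma=0.2)
    defaults.update(kw)
    return SectionParams(**defaults)


@pytest.fixture(scope="session")
def small_control_bundle():
    """One small lesion-free synthetic section, shared across tests."""
    return simulate_section(small_params())


@pytest.fixture(scope="session")
def small_lesion_bundle():
    """One small fibrotic synthetic section (30% coverage, no vessels)."""
    return simulate_section(small_params(lesion_coverage=0.3, seed=12, n_vessels=0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
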