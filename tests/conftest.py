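import warnings

import numpy as np
import pytest

import snpmetrics as sm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160211)


@pytest.fixture(scope="session")
def small_study():
    """A small two-stage study with the default planted effects."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.simulate_study(sm.SimulationConfig(seed=11, m_snps=300))


@pytest.fixture(scope="session")
def null_study():
    """A study with every genetic and covariate effect switched off."""
    cfg = sm.SimulationConfig(
        seed=5,
        m_snps=400,
        causal_snps=(),
        apoe_or_het=1.0,
        apoe_or_hom=1.0,
        covariate_effects={},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.simulate_study(cfg)


@pytest.fixture(autouse=True)
def _quiet_separation_warnings():
    """Model-fit warnings on tiny synthetic fixtures are expected noise."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="possible separation")
        warnings.filterwarnings("ignore", message="comorbidity matching")
        warnings.filterwarnings("ignore", message="dropping .* uninformative")
        yield
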