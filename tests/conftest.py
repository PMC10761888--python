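import numpy as np
import pytest

from neckfda import GeneratorConfig
from neckfda.simulate import generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240102)


@pytest.fixture(scope="session")
def analytic_study():
    """55-observation cohort carrying only the analytic basis curves."""
    cfg = GeneratorConfig(seed=42, n_subjects=55, sessions_per_subject=1)
    return generate_dataset(cfg, curves_only=True)


@pytest.fixture(scope="session")
def recorded_study():
    """Smaller cohort with raw records run through the full preprocessing."""
    cfg = GeneratorConfig(seed=11, n_subjects=10, sessions_per_subject=2)
    return generate_dataset(cfg)
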