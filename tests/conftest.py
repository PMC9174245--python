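import numpy as np
import pytest
from hypothesis import settings

from btcmeth.simulate import CohortSpec, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def strong_cohort():
    """High-effect cohort: delta 0.4, kappa 100, pure tumours, 20v10."""
    spec = CohortSpec(
        n_tumour=20, n_normal=10, n_cgis=60, probes_per_cgi=(4, 8),
        n_hyper=8, n_hypo=1, delta=0.4, kappa=100.0,
        purity_range=(1.0, 1.0), seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240301)
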