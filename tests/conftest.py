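import numpy as np
import pytest
from hypothesis import settings

import connpls as cp

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def planted_cohort():
    """Sized-down cohort with a strong planted latent component.

    12 regions (66 edges), 80 patients, latent effect 3 on a 50-edge support:
    the regime where the rank-1 signal dominates the noise singular values so
    salience recovery is expected.
    """
    spec = cp.CohortSpec(
        n_regions=12, n_patients=80, n_controls=60,
        latent_effect=3.0, n_support_edges=50, seed=7,
    )
    return cp.generate_cohort(spec)


@pytest.fixture(scope="session")
def fitted_planted(planted_cohort):
    c = planted_cohort
    return cp.fit_plsc(c.X_patients, c.Y_patients)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
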