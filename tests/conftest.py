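"""Shared fixtures: fixture tables, phantom renderings, simulated cohorts.

Session-scoped fixtures hold the expensive renders so that unit and
acceptance tests share them.
"""

from dataclasses import replace

import numpy as np
import pytest

from cacscore.pipeline import load_fixture_table
from cacscore.synthetic import (
    GATED_PROTOCOL,
    LDCT_PROTOCOL,
    CohortSpec,
    PhantomSpec,
    generate_cohort,
    rasterize_phantom,
)

COHORT_SEED = 7
COHORT_N = 60


@pytest.fixture(scope="session")
def tables():
    """The three published 6x6 confusion matrices (test rows x reference)."""
    return {name: load_fixture_table(f"table6{name}.csv") for name in "ABC"}


@pytest.fixture(scope="session")
def noise_free_phantoms():
    """Phantom rendered under both protocols with noise switched off."""
    spec = PhantomSpec()
    p120 = rasterize_phantom(spec, replace(GATED_PROTOCOL, noise_sd=0.0), supersample=4)
    p130 = rasterize_phantom(spec, replace(LDCT_PROTOCOL, noise_sd=0.0), supersample=4)
    return spec, p120, p130


@pytest.fixture(scope="session")
def cohort_default():
    """n=60 paired cohort under the default (study) protocols, fixed seed."""
    spec = CohortSpec(n_subjects=COHORT_N, seed=COHORT_SEED)
    return generate_cohort(spec, GATED_PROTOCOL, LDCT_PROTOCOL)


@pytest.fixture(scope="session")
def cohort_noise_free_gated():
    """Same cohort conditions but with a noise-free gated protocol."""
    spec = CohortSpec(n_subjects=COHORT_N, seed=COHORT_SEED)
    gated = replace(GATED_PROTOCOL, noise_sd=0.0)
    return generate_cohort(spec, gated, LDCT_PROTOCOL)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
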