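import dataclasses

import pytest

from failtiming.cohort import default_params, generate_cohort
from failtiming.survival import derive_endpoints


@pytest.fixture(scope="session")
def cohort10k():
    """One large default-condition cohort shared by calibration checks."""
    params = default_params(n_patients=10_000, seed=20240917)
    return params, generate_cohort(params)


@pytest.fixture(scope="session")
def endpoints10k(cohort10k):
    _, cohort = cohort10k
    return derive_endpoints(cohort)


@pytest.fixture(scope="session")
def small_cohort():
    params = default_params(n_patients=400, seed=11)
    return generate_cohort(params)


@pytest.fixture()
def balanced_params():
    """Default conditions with equal allocation over the dose groups."""
    p = default_params()
    marginals = dict(p.covariate_marginals)
    marginals["ccd_group"] = {"0": 1 / 3, "1-200": 1 / 3, ">200": 1 / 3}
    return dataclasses.replace(p, covariate_marginals=marginals)
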