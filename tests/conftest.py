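import numpy as np
import pytest

from shapstrat import generate_cohort, run_pipeline


@pytest.fixture(scope="session")
def cohort300():
    """Default synthetic cohort: four planted immune subclasses, n = 300."""
    return generate_cohort(n=300, seed=1)


@pytest.fixture(scope="session")
def pipeline300(cohort300):
    """Full pipeline result (DEG -> classifier -> SHAP -> clustering) on cohort300."""
    return run_pipeline(cohort300.expr, cohort300.clinical, cohort300.mutations, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheaper cohort for protocol-level tests."""
    return generate_cohort(n=120, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
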