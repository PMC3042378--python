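import numpy as np
import pandas as pd
import pytest

from pthpath import (
    McmcConfig,
    build_final_model,
    build_initial_model,
    generate_cohort,
    reference_config,
)


@pytest.fixture(scope="session")
def initial_model():
    return build_initial_model()


@pytest.fixture(scope="session")
def final_model():
    return build_final_model()


@pytest.fixture(scope="session")
def reference_cohort(final_model):
    """One n=971 cohort simulated from the reference calibration."""
    return generate_cohort(final_model, reference_config(n=971, seed=20240917))


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short chains for tests where posterior precision is not the point."""
    return McmcConfig(chains=3, iterations=1500, burnin=500, seed=5)


@pytest.fixture(scope="session")
def reference_fit(final_model, reference_cohort, fast_mcmc):
    """A shared short fit of the final model on the reference cohort."""
    from pthpath import sample_posterior

    return sample_posterior(final_model, reference_cohort, config=fast_mcmc)
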