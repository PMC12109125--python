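import numpy as np
import pytest

from bcrfusion.io_data import default_schema
from bcrfusion.pipeline import prepare_cohort
from bcrfusion.synthetic import PhantomParams, generate_cohort


@pytest.fixture(scope="session")
def small_params():
    # higher prevalence than the study default so a 12-patient cohort always
    # contains enough of both classes for split/CV fixtures
    return PhantomParams(n_patients=12, prevalence=0.4, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params)


@pytest.fixture(scope="session")
def small_samples(small_cohort):
    samples, labels = prepare_cohort(small_cohort)
    return samples, labels


@pytest.fixture(scope="session")
def schema():
    return default_schema()


def numeric_gradient(f, x, eps=1e-6):
    """Central-difference gradient of a scalar function of array x."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
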