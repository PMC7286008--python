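import numpy as np
import pytest

from protonsct.phantom import PhantomSpec, make_phantom
from protonsct.dose import make_plan, compute_plan_dose


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def sample(spec):
    """One default head phantom shared across read-only tests."""
    return make_phantom(spec, seed=7)


@pytest.fixture(scope="session")
def plan_and_dose(sample):
    plan = make_plan(sample.ct, sample.masks["CTV"])
    dose = compute_plan_dose(plan, sample.ct)
    return plan, dose


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
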