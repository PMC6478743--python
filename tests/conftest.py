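import numpy as np
import pytest

from mmsv.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """A medium synthetic cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_samples=250), seed=101)


@pytest.fixture(scope="session")
def small_cohort_qc():
    """A small cohort together with its full QC result (genome-backed)."""
    from mmsv import qc

    c = generate_cohort(CohortConfig(n_samples=60), seed=7)
    result = qc.apply_qc(c.calls, c.genome, c.mappability, c.annotations)
    return c, result


@pytest.fixture()
def rng():
    return np.random.default_rng(20_19)
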