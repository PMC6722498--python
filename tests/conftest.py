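import numpy as np
import pytest

from endoxpred.metabolites import ANALYTES, ENDOXIFEN, MetabolitePanel
from endoxpred.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-sample cohort with default study-structure parameters."""
    return generate_cohort(CohortConfig(n_samples=400, n_null_snps=40, seed=20_240_101))


@pytest.fixture()
def rng():
    return np.random.default_rng(987)


def random_panel(rng, sample_id="S0"):
    conc = {a: float(rng.uniform(0.5, 200.0)) for a in ANALYTES}
    return MetabolitePanel(sample_id, conc)


def random_panels(rng, n):
    return [random_panel(rng, f"S{i}") for i in range(n)]
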