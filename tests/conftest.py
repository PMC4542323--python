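import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from twingraph import SimulationSpec, generate_cohort


@pytest.fixture(scope="session")
def ae_cohort_2000():
    """Univariate a2 = 0.6 / e2 = 0.4 cohort, 2000 pairs per zygosity."""
    spec = SimulationSpec(
        n_mz_pairs=2000, n_dz_pairs=2000, phenotype_labels=["x"],
        A_cov=np.array([[0.6]]), E_cov=np.array([[0.4]]), seed=20260925)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_mixed_cohort():
    """Small mixed cohort with singletons, for likelihood oracle checks."""
    spec = SimulationSpec(
        n_mz_pairs=15, n_dz_pairs=12, n_singletons=7,
        phenotype_labels=["u", "v"],
        A_cov=np.array([[0.5, 0.2], [0.2, 0.4]]),
        C_cov=np.array([[0.1, 0.05], [0.05, 0.1]]),
        E_cov=np.array([[0.4, 0.1], [0.1, 0.5]]),
        seed=77)
    return generate_cohort(spec)
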