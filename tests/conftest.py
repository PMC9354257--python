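import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tacpk.cohort import CohortSpec, simulate_cohort
from tacpk.core_model import final_model
from tacpk.io import Dataset


@pytest.fixture(scope="session")
def model():
    """The published final model parameterization."""
    return final_model()


@pytest.fixture(scope="session")
def cohort(model):
    """A reference 18-subject synthetic cohort (fixed seed)."""
    dataset, subjects = simulate_cohort(CohortSpec(seed=20220722), model)
    return dataset, subjects


@pytest.fixture(scope="session")
def fitted(cohort, model):
    """The reference cohort fitted once, shared across tests."""
    from tacpk.estimation import fit

    dataset, _ = cohort
    result = fit(dataset, model, compute_se=False)
    assert result.converged
    return result


def make_events(rows):
    """Build a Dataset from (ID, TIME, AMT, EVID, MDV, DV, WT) tuples."""
    frame = pd.DataFrame(
        rows, columns=["ID", "TIME", "AMT", "EVID", "MDV", "DV", "WT"]
    )
    return Dataset(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
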