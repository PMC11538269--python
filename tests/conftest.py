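import numpy as np
import pytest

from retinapair import pretrain as pt
from retinapair import splits as sp
from retinapair import synthdata as sd


@pytest.fixture(scope="session")
def small_cohort():
    """40-patient cohort shared by fast tests (2 visits for pair-sampler tests)."""
    cfg = sd.SyntheticCohortConfig(n_patients=40, visits_per_patient=(1, 2), seed=5)
    return sd.generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def small_manifest(small_cohort):
    scans, _ = small_cohort
    return sd.cohort_manifest(scans)


@pytest.fixture(scope="session")
def small_data(small_cohort):
    scans, _ = small_cohort
    return pt.build_training_arrays(scans)


@pytest.fixture(scope="session")
def small_split(small_manifest):
    return sp.assign_splits(small_manifest, (0.7, 0.15, 0.15), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
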