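import warnings

import numpy as np
import pytest

from lsmpipe import synthetic_data as syn
from lsmpipe.io_model import AnalysisConfig, LesionMask

warnings.filterwarnings("ignore", message=".*Solver terminated early.*")


@pytest.fixture(scope="session")
def truth():
    return syn.default_ground_truth()


@pytest.fixture(scope="session")
def truth_effect():
    return syn.default_ground_truth(effect_size=10.0, noise_sd=0.5)


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig(svr_kernel="linear", rng_seed=0)


@pytest.fixture(scope="session")
def small_cohort(truth):
    masks, cohort = syn.generate_lesion_cohort(20, truth.grid_shape, truth, seed=11)
    return masks, cohort


@pytest.fixture(scope="session")
def normative_runs(truth):
    return syn.generate_normative_timeseries(4, 1, 80, 0.72, truth, seed=21)


@pytest.fixture(scope="session")
def cleaned_runs(normative_runs, config):
    from lsmpipe import lnsm

    return [lnsm.preprocess_run(r, config) for r in normative_runs]


def make_mask(shape=(8, 8, 8), voxels=(), affine=None, patient_id="sub-001"):
    grid = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        grid[tuple(v)] = 1
    if affine is None:
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
    return LesionMask(patient_id=patient_id, grid=grid, affine=affine)
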