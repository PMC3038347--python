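import numpy as np
import pytest

from occurange import (assign_methods, generate_covariates, generate_truth,
                       simulate_incidental, simulate_surveys)
from occurange.design import SurveyDesign
from occurange.synthetic import DEFAULT_SCENARIO

P_TRUE = DEFAULT_SCENARIO["p_true"]
BETA = {"cov1": 2.0, "cov2": -1.5, "cov3": 0.0}


@pytest.fixture(scope="session")
def landscape():
    return generate_covariates(60, 60, 3, smoothness=4, seed=101)


@pytest.fixture(scope="session")
def truth(landscape):
    return generate_truth(landscape, BETA, P_TRUE, alpha=1.0, seed=102)


@pytest.fixture(scope="session")
def sightings(truth):
    return simulate_incidental(truth, 300, seed=103)


def make_history(truth, n_sites, seed, camera_fraction=0.5):
    """Detection history at uniformly sampled cells of the truth grid."""
    rng = np.random.default_rng(seed)
    n_cells = truth.grid.n_rows * truth.grid.n_cols
    ids = rng.choice(n_cells, n_sites, replace=False)
    design = SurveyDesign(ids, np.array(["srs"] * n_sites, dtype=object),
                          truth.grid.shape)
    design = assign_methods(design,
                            n_camera_cells=int(n_sites * camera_fraction),
                            seed=seed + 1)
    return simulate_surveys(design, truth, seed=seed + 2), design


@pytest.fixture(scope="session")
def survey_history(truth):
    history, _ = make_history(truth, 200, seed=110)
    return history
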