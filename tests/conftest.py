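from dataclasses import replace

import numpy as np
import pytest

import mixshape as ms

# FA-like component geometry shared across tests
MU = (-0.26, 0.78)
SIGMA = 0.87
TAU_ALL = (0.7488, 0.2512)


@pytest.fixture()
def fa_params():
    return ms.GMMParams(mu=np.array(MU), sigma=SIGMA, tau=np.array(TAU_ALL))


@pytest.fixture()
def small_cohort():
    """A quick paper-like cohort: 28 subjects, 800 voxels."""
    cfg = replace(ms.scenario_presets()["paper_like"], n_voxels=800, seed=11)
    return ms.generate_cohort(cfg)


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(4, 30))
    return ms.SubjectVoxelMatrix(
        values=vals, subject_ids=[f"s{i}" for i in range(4)], standardized=True
    )
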