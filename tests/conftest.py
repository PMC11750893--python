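import warnings

import numpy as np
import pytest

from vcohort import (GeneratorConfig, align_calcifications, align_cohort, fit,
                     make_cohort, resample)


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-subject reduced-resolution synthetic cohort with ground truth."""
    cfg = GeneratorConfig(n_patients=12, wall_points=500, calc_points=400,
                          seed=7)
    samples, truth = make_cohort(cfg)
    return samples, truth


@pytest.fixture(scope="session")
def aligned_wall(small_cohort):
    samples, _ = small_cohort
    walls = [resample(s.wall, 400, seed=i) for i, s in enumerate(samples)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return align_cohort(walls)


@pytest.fixture(scope="session")
def aligned_calc(small_cohort, aligned_wall):
    samples, _ = small_cohort
    calcs = [resample(s.calcification, 300, seed=100 + i)
             for i, s in enumerate(samples)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return align_calcifications(calcs, aligned_wall)


@pytest.fixture(scope="session")
def wall_model(aligned_wall):
    return fit(aligned_wall)


@pytest.fixture(scope="session")
def calc_model(aligned_calc):
    return fit(aligned_calc)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
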