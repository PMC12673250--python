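import numpy as np
import pandas as pd
import pytest

from oreamnos.coefficients import PARTURITION_SPEC
from oreamnos.data_model import DEFAULT_AGE_CLASSES, build_analysis_table
from oreamnos.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic mark-resight dataset (60 females, 8 years)."""
    return generate(GeneratorConfig(n_individuals=60, n_years=8, seed=314))


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale synthetic dataset (180 females, 17 years)."""
    return generate(GeneratorConfig(seed=2718))


@pytest.fixture(scope="session")
def parturition_table(study_dataset):
    return build_analysis_table(
        study_dataset.records, study_dataset.climate, "parturition", DEFAULT_AGE_CLASSES
    ).table


@pytest.fixture(scope="session")
def grouped_bernoulli():
    """Tiny 5-group, 4-obs/group random-intercept dataset with design matrix."""
    rng = np.random.default_rng(99)
    n_groups, per = 5, 4
    gi = np.repeat(np.arange(n_groups), per)
    x = rng.normal(size=n_groups * per)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.array([0.3, -0.8])
    sigma = 0.9
    u = rng.normal(0, sigma, n_groups)
    p = 1 / (1 + np.exp(-(X @ beta + u[gi])))
    y = (rng.random(len(p)) < p).astype(float)
    return {"X": X, "y": y, "group_idx": gi, "beta": beta, "sigma": sigma}
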