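import numpy as np
import pytest

import methylpredict as mp


@pytest.fixture(scope="session")
def small_cfg():
    return mp.SynthConfig(
        n_samples=200,
        n_cpgs=800,
        n_genes=120,
        n_sets=10,
        age_cpgs=60,
        smoking_cpgs=40,
        bmi_cpgs=30,
        alcohol_cpgs=30,
        ancestry_cpgs=10,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_ann(small_cfg):
    return mp.generate_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_ann):
    return mp.generate_cohort(small_cfg, small_ann)


@pytest.fixture(scope="session")
def small_m(small_cohort):
    mat, _ = small_cohort
    return mp.beta_to_m(mat)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
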