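import numpy as np
import pytest

from gaitpattern import (
    SynthConfig,
    build_feature_matrix,
    generate_cohort,
    standardize,
)


@pytest.fixture(scope="session")
def small_cohort():
    """4 subjects x 4 conditions x 3 trials x 2 sides, short cycles."""
    cfg = SynthConfig(n_subjects=4, n_conditions=4, n_trials=3, n_time=41, seed=7)
    trials, truth = generate_cohort(cfg)
    return cfg, trials, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    cfg, trials, _ = small_cohort
    fm = build_feature_matrix(trials, n_time=cfg.n_time)
    fm_std, params = standardize(fm)
    return fm, fm_std, params


@pytest.fixture()
def rng():
    return np.random.default_rng(20150813 % 2**31)
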