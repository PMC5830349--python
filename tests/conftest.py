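import warnings

import numpy as np
import pytest

from featattn.pipeline import SubjectConfig, analyze_subject, simulate_subject


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study conditions used by the slower end-to-end tests."""
    return SubjectConfig(n_runs=3, trials_per_run=30, n_voxels=120)


@pytest.fixture(scope="session")
def small_subject(small_config):
    return simulate_subject(small_config, seed=42)


@pytest.fixture(scope="session")
def small_subject_result(small_subject):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return analyze_subject(small_subject)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
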