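import numpy as np
import pytest

import facesym as fs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def template_case():
    return fs.make_template()


@pytest.fixture(scope="session")
def default_cohort_summary():
    """The full 15-case synthetic experiment at a fixed seed (shared:
    the pipeline runs once per session)."""
    return fs.run_experiment(fs.ExperimentConfig(seed=1))
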