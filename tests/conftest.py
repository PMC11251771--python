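import warnings

import pytest

from lans.config import load_threshold_config
from lans.simulate import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def mayo_cfg():
    return load_threshold_config(None, "MAYO")


@pytest.fixture(scope="session")
def adni_cfg():
    return load_threshold_config(None, "ADNI")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-sized synthetic cohort (165 patients), fixed seed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(GeneratorConfig(seed=0))
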