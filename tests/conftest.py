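import numpy as np
import pytest

from hydrokin import datasets


@pytest.fixture(scope="session")
def assay():
    return datasets.default_assay()


@pytest.fixture(scope="session")
def design_points():
    return datasets.study_design().coded


@pytest.fixture(scope="session")
def constants():
    return datasets.load_kinetic_constants()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
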