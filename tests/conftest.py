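import pytest
from hypothesis import settings

from shprotect import (
    CoenzymeBinding,
    ExperimentDesign,
    InactivationParams,
    NoiseSpec,
    SignalModel,
)
from shprotect.catalog import reference_catalog
from shprotect.units import mM, uM

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    return reference_catalog()


@pytest.fixture(scope="session")
def wt_params(catalog):
    return catalog["wild-type"].params


@pytest.fixture(scope="session")
def f238s_params(catalog):
    return catalog["F238S"].params


@pytest.fixture(scope="session")
def wt_nad(catalog):
    return catalog["wild-type"].bindings["NAD+"]


@pytest.fixture
def design():
    return ExperimentDesign()


@pytest.fixture
def no_noise():
    return NoiseSpec()


@pytest.fixture
def activity_sig():
    return SignalModel(mode="activity")


@pytest.fixture
def absorbance_sig():
    return SignalModel(mode="absorbance", sh_conc=2 * uM)
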