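import numpy as np
import pytest

from psorseq import PsoriasisCEModel
from psorseq.params import LifeTable, ParameterSet, load_parameters, default_parameter_path


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """The bundled psoriasis parameter fixture."""
    return load_parameters(default_parameter_path())


@pytest.fixture(scope="session")
def model(params) -> PsoriasisCEModel:
    return PsoriasisCEModel(params)


@pytest.fixture(scope="session")
def fitted(model):
    """Base-case fit; the unpublished BSC cost resolves at the feasibility
    boundary for this fixture (see the calibration note)."""
    return model.fit()


@pytest.fixture()
def zero_mortality(params) -> ParameterSet:
    """Fixture inputs with an immortal-until-max-age life table."""
    from dataclasses import replace
    ages = np.arange(0, 111)
    return replace(params, lifetable=LifeTable(ages, np.zeros_like(ages, dtype=float)))
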