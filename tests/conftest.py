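import numpy as np
import pytest

from memswitch.gene_model import GeneModel, make_uniform_gene
from memswitch.kinetics import (
    MEMORY_SWITCH,
    MODEL1,
    InductionProtocol,
    KineticParams,
    PromoterModelSpec,
)


@pytest.fixture(scope="session")
def gene() -> GeneModel:
    return make_uniform_gene(67, 4500)


@pytest.fixture(scope="session")
def memory_spec() -> PromoterModelSpec:
    return PromoterModelSpec(MEMORY_SWITCH)


@pytest.fixture(scope="session")
def model1_spec() -> PromoterModelSpec:
    return PromoterModelSpec(MODEL1)


@pytest.fixture()
def default_params() -> KineticParams:
    return KineticParams()


@pytest.fixture(scope="session")
def standard_protocol() -> InductionProtocol:
    return InductionProtocol.standard()
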