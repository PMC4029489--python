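import numpy as np
import pytest

from mdscea.costing import StateCostBundle, reference_bundles
from mdscea.markov import ArmSpec, ModelConfig
from mdscea.survival import ParametricSurvModel


@pytest.fixture(scope="session")
def bundles():
    return reference_bundles()


@pytest.fixture()
def aza_like_spec(bundles) -> ArmSpec:
    """An azacitidine-like arm built from closed-form models (no fitting)."""
    return ArmSpec(
        label="AZA",
        os_model=ParametricSurvModel.lognormal(np.log(745.0), 1.1),
        aml_model=ParametricSurvModel.lognormal(np.log(541.0), 1.0),
        cess_model=ParametricSurvModel.weibull(1.3, 420.0),
        costs=bundles["AZA"],
        utility_mds=0.67,
        utility_aml=0.52,
    )


@pytest.fixture()
def bsc_like_spec(bundles) -> ArmSpec:
    return ArmSpec(
        label="BSC",
        os_model=ParametricSurvModel.lognormal(np.log(353.0), 1.1),
        aml_model=ParametricSurvModel.lognormal(np.log(350.0), 1.0),
        cess_model=ParametricSurvModel.weibull(1.3, 240.0),
        costs=bundles["BSC"],
        utility_mds=0.67,
        utility_aml=0.52,
    )


@pytest.fixture()
def zero_cost_bundle() -> StateCostBundle:
    return StateCostBundle(mds_on={}, mds_off={}, aml={})


@pytest.fixture()
def config() -> ModelConfig:
    return ModelConfig()
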