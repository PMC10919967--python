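import numpy as np
import pandas as pd
import pytest

from radsurv import (
    BaselineRateTable,
    ExposureProfile,
    RADSSettings,
    RiskModelSpec,
)
from radsurv.reporting import packaged_weight_sets
from radsurv.risk_models import FAMILY_COEFFICIENTS
from radsurv.synthetic import (
    SyntheticConfig,
    generate_baseline,
    generate_model_registry,
)


def make_spec(family: str, endpoint: str = "ERR", covariance=None, **coeffs
              ) -> RiskModelSpec:
    """Spec with unspecified coefficients zero and zero covariance."""
    names = FAMILY_COEFFICIENTS[family]
    full = {name: float(coeffs.get(name, 0.0)) for name in names}
    unknown = set(coeffs) - set(names)
    if unknown:
        raise AssertionError(f"bad test coefficients {unknown}")
    cov = np.zeros((len(names), len(names))) if covariance is None \
        else np.asarray(covariance, dtype=float)
    return RiskModelSpec(family, endpoint, full, cov)


def flat_baseline(rate_per_100000: float = 1000.0) -> BaselineRateTable:
    """Constant-rate baseline over ages 0-100, both sexes."""
    rows = [{"age": float(a), "sex": sex, "rate_per_100000": rate_per_100000}
            for a in range(0, 101) for sex in ("male", "female")]
    return BaselineRateTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def syn_config() -> SyntheticConfig:
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def registry(syn_config):
    return generate_model_registry(syn_config)


@pytest.fixture(scope="session")
def baseline(syn_config):
    return generate_baseline(syn_config)


@pytest.fixture(scope="session")
def weight_sets():
    return packaged_weight_sets()


@pytest.fixture()
def lunar_male() -> ExposureProfile:
    return ExposureProfile(0.17, 40.0, 65.0, "male")


@pytest.fixture()
def mars_female() -> ExposureProfile:
    return ExposureProfile(1.0, 40.0, 65.0, "female")


@pytest.fixture()
def settings() -> RADSSettings:
    return RADSSettings(seed=0)
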