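import logging

import pytest

from radiocsc import (
    IMKParameters,
    LQParameters,
    MicrodosimetricSpec,
    MixtureModel,
)

logging.getLogger("radiocsc").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def spec() -> MicrodosimetricSpec:
    """Kilovoltage X-ray site spec: y_D = 4.68 keV/um, 1 um water site."""
    return MicrodosimetricSpec(y_d=4.68, rho=1.0, site_diameter_um=1.0)


@pytest.fixture(scope="session")
def du145_mixture() -> MixtureModel:
    """Fitted brain-metastatic prostate-line mixture parameters
    (alpha0_pc=0.332, beta0_pc=0.055, alpha0_csc=0.007, beta0_csc=0.002,
    f_csc=0.183%)."""
    return MixtureModel(
        pc=IMKParameters(alpha0=0.332, beta0=0.055),
        csc=IMKParameters(alpha0=0.007, beta0=0.002),
        f_csc=0.00183,
    )


@pytest.fixture(scope="session")
def pc3_mixture() -> MixtureModel:
    """Fitted bone-metastatic prostate-line mixture parameters."""
    return MixtureModel(
        pc=IMKParameters(alpha0=0.076, beta0=0.108),
        csc=IMKParameters(alpha0=0.065, beta0=0.025),
        f_csc=0.01984,
    )


@pytest.fixture(scope="session")
def du145_lq() -> LQParameters:
    return LQParameters(alpha=0.658, beta=0.002)


@pytest.fixture(scope="session")
def pc3_lq() -> LQParameters:
    return LQParameters(alpha=0.551, beta=0.021)
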