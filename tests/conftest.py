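import numpy as np
import pytest

from mirswitch import (
    FeedbackParams,
    LogNormalMixture,
    RandomSpec,
    ReporterCalibration,
    SwitchingRates,
)

# fitted per-division switching rates of the two-state system
K_HL, K_LH = 0.072, 0.048
# colony-simulation parameter set: k_hl + k_lh = 0.08 with k_hl = 1.5 k_lh
K_HL_SIM, K_LH_SIM = 0.048, 0.032


@pytest.fixture
def calib():
    """Reporter calibration with a near-non-cooperative Hill coefficient."""
    return ReporterCalibration(K=5.0, n=1.07)


@pytest.fixture
def rates():
    return SwitchingRates(k_hl=K_HL, k_lh=K_LH)


@pytest.fixture
def sim_rates():
    return SwitchingRates(k_hl=K_HL_SIM, k_lh=K_LH_SIM)


@pytest.fixture
def bimodal_mixture():
    """Well-separated two-state mixture: component medians 10-fold apart."""
    return LogNormalMixture(
        w_high=0.6, w_low=0.4,
        mu_high=float(np.log(0.08)), mu_low=float(np.log(0.8)),
        sigma_high=0.3, sigma_low=0.3,
    )


@pytest.fixture
def feedback_params():
    """Reference bistable parameter set (alpha=12, beta=10, gamma=1)."""
    return FeedbackParams(alpha=12.0, beta=10.0, gamma=1.0)


@pytest.fixture
def rng():
    return RandomSpec(seed=20240901, stream_id="tests")
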