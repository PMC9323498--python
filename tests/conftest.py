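import numpy as np
import pytest
from scipy.optimize import brentq

from quenchbind import TitrationGroundTruth, simulate_titration


def mass_action_bound_bruteforce(Ka: float, P0: float, Q0: float) -> float:
    """Independent oracle: solve Ka(P0-x)(Q0-x) = x by bracketed root find."""
    if Q0 == 0:
        return 0.0

    def g(x):
        return Ka * (P0 - x) * (Q0 - x) - x

    return brentq(g, 0.0, min(P0, Q0), xtol=1e-24, rtol=1e-15)


@pytest.fixture
def static_series_noise_free():
    """Noise-free 1:1 static titration at the study conditions."""
    truth = TitrationGroundTruth(Ka=4.3e4)
    return truth, simulate_titration(truth, 298.0)


@pytest.fixture
def dynamic_series_noise_free():
    truth = TitrationGroundTruth(
        Ka=1.0, mode="dynamic", KD_collisional=3.69e4
    )
    return truth, simulate_titration(truth, 298.0)
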