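import numpy as np
import pytest

from fdgflux import (AcquisitionProtocol, CompartmentParams, FrameTiming,
                     InputFunction, ParametricInput)


class StepInput(InputFunction):
    """Constant plasma concentration from t=0 — the textbook step input."""

    def __init__(self, level: float = 10.0):
        self.level = float(level)

    def conc(self, t):
        return np.full_like(np.asarray(t, dtype=float), self.level)

    def cumint(self, t):
        return self.level * np.asarray(t, dtype=float)

    def cumint2(self, t):
        return 0.5 * self.level * np.asarray(t, dtype=float) ** 2

    def expconv(self, lam, t):
        t = np.asarray(t, dtype=float)
        if lam <= 0:
            return self.cumint(t)
        return self.level * (1.0 - np.exp(-lam * t)) / lam


@pytest.fixture
def protocol():
    return AcquisitionProtocol()

@pytest.fixture
def timing60():
    return FrameTiming.uniform(60, 1.0)

@pytest.fixture
def step_input():
    return StepInput(10.0)

@pytest.fixture
def infusion_input():
    """Typical constant-infusion input curve."""
    return ParametricInput(plateau=74.0, tau=20.0, bolus_amp=33.5, bolus_tau=1.5)

@pytest.fixture
def myo_params():
    return CompartmentParams(0.6, 1.2, 0.1, 0.0, 0.2, 0.1)
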