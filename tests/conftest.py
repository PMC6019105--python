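import numpy as np
import pytest

import zflume as z


def fit_meter_cals(hw):
    """Bucket-test both simulated meters of a rig and fit their lines."""
    cals = []
    for m in (hw.meter1, hw.meter2):
        flows = [m.offset_flow + m.ml_per_pulse * r for r in np.linspace(1, 75, 10)]
        cals.append(z.fit_meter(z.bucket_test(m, flows, window=60.0),
                                meter_id=m.meter_id))
    return tuple(cals)


@pytest.fixture
def fast_hw():
    return z.fast_scenario(noise_sd=0.0)


@pytest.fixture
def slow_hw():
    return z.slow_scenario(noise_sd=0.0)


@pytest.fixture
def meter_cals(fast_hw):
    return fit_meter_cals(fast_hw)


@pytest.fixture
def fast_controller(fast_hw):
    """Noiseless fast-regime controller, fully calibrated."""
    ctrl = z.FlumeController(fast_hw, regime="fast", meter_cals=fit_meter_cals(fast_hw))
    ctrl.set_pwm_cal(z.fit_pwm(z.run_pwm_sweep(ctrl), regime="fast"))
    return ctrl


@pytest.fixture
def slow_controller(slow_hw):
    """Noiseless slow-regime controller, fully calibrated."""
    ctrl = z.FlumeController(slow_hw, regime="slow", meter_cals=fit_meter_cals(slow_hw))
    ctrl.set_pwm_cal(z.fit_pwm(z.run_pwm_sweep(ctrl), regime="slow"))
    return ctrl


@pytest.fixture(scope="session")
def presets():
    return z.load_presets()
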