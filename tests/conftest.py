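import numpy as np
import pytest

from frtkin import PitchSeries, SensorTrace, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def noise_free_config():
    return SimulationConfig(
        sensor_noise_sd=0.0, attitude_noise_sd_deg=0.0, gyro_noise_sd_dps=0.0
    )


def make_series(values, rate=32.0, t0=0.0):
    return PitchSeries(rate=rate, t0=t0, values=np.asarray(values, float))


def make_trace(t, acc=None, gyro=None, attitude=None, rate=32.0, placement="trunk"):
    return SensorTrace(
        t=np.asarray(t, float), acc=acc, gyro=gyro, attitude=attitude,
        placement=placement, nominal_rate=rate,
    )


def trapezoid_series(rate=32.0, peak=15.0, rise=(1.0, 3.0), fall=(4.0, 6.0), total=7.0):
    """0 until rise[0], linear to peak at rise[1], plateau, linear back to 0
    at fall[1]; the analytic shape used in the segmentation examples."""
    t = np.arange(int(round(total * rate)) + 1) / rate
    v = np.interp(t, [0.0, rise[0], rise[1], fall[0], fall[1], total],
                  [0.0, 0.0, peak, peak, 0.0, 0.0])
    return make_series(v, rate=rate), t
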