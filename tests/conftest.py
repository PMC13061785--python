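import numpy as np
import pytest

from fesloop.controller import build_gait_config, build_pedaling_config
from fesloop.imu import AngleTrace, ImuSample


@pytest.fixture
def pedaling_config():
    return build_pedaling_config()


@pytest.fixture
def gait_config():
    return build_gait_config()


@pytest.fixture
def sweep_samples():
    """Noise-free monotone angle sweep through one pedaling revolution.

    The angle advances uniformly from -180 deg through a full turn at 20 Hz
    over 2.5 s, which is the reference input for phase-sequence checks.
    """

    def make(period: float = 2.5, rate: float = 20.0, n_rev: int = 1):
        t = np.arange(int(period * rate * n_rev)) / rate
        psi = np.radians(-180.0 + 360.0 * t / period)
        return [
            ImuSample(float(tt), float(np.sin(p)), float(np.cos(p)))
            for tt, p in zip(t, psi)
        ]

    return make


@pytest.fixture
def angle_trace_of():
    def make(theta, rate: float = 20.0):
        theta = np.asarray(theta, dtype=float)
        return AngleTrace(t=np.arange(theta.size) / rate, theta=theta)

    return make
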