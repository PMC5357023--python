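import numpy as np
import pytest

from lifopt import DimensionConfig, NoiseModel, ResponseSurface, Scenario


@pytest.fixture
def table1_configs():
    """The two-attribute rating-study configuration shipped as the default."""
    return [
        DimensionConfig(omega=2.63, delta=8.0, gamma=0.0006, n_window=150,
                        x_init=20.0, lo=1.0, hi=100.0),
        DimensionConfig(omega=2.51, delta=8.0, gamma=0.0006, n_window=150,
                        x_init=20.0, lo=1.0, hi=100.0),
    ]


@pytest.fixture
def wholeperiod_config():
    """1-D config whose window spans exactly 5 dither periods (no leakage)."""
    return DimensionConfig(omega=2 * np.pi / 10, delta=8.0, gamma=0.0006,
                           n_window=50, x_init=45.0, lo=1.0, hi=100.0)


@pytest.fixture
def noiseless_scenario():
    return Scenario(
        surface=ResponseSurface(a1=-0.01, a2=-0.02, x1m=55.0, x2m=60.0, y0=70.0),
        noise=NoiseModel(kind="none"),
        n_trials=3600,
    )


def quadratic_window(a1, delta, d, omega, n, y0=70.0, start=1):
    """Noiseless 1-D quadratic responses over one demodulation window.

    Independent of the controller: evaluates y_i = a1*(d + delta*cos(omega*i))^2 + y0
    directly for i = start..start+n-1 and returns [(i, y_i)] pairs.
    """
    i = np.arange(start, start + n)
    y = a1 * (d + delta * np.cos(omega * i)) ** 2 + y0
    return list(zip(i.tolist(), y.tolist()))
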