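import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

from oxaribo.synthetic_data import default_oxa1_config


@pytest.fixture
def study_config():
    return default_oxa1_config()


@pytest.fixture
def noiseless_config():
    return dataclasses.replace(
        default_oxa1_config(),
        shift_noise_sd=0.0,
        intensity_noise_sd=0.0,
        mst_noise_fraction=0.0,
    )


def mass_action_fraction_bound(a: float, b: float, kd: float) -> float:
    """Independent oracle: solve (a - x)(b - x) = kd * x for the complex
    concentration x by bracketing bisection, then FB = x / b.

    Deliberately avoids the closed-form quadratic root used by the package.
    """
    if a == 0:
        return 0.0
    if kd == 0:
        return min(a, b) / b

    def balance(x):
        return (a - x) * (b - x) - kd * x

    hi = min(a, b)
    # balance(0) = ab > 0 and balance(hi) = -kd*hi < 0: a root is bracketed
    x = brentq(balance, 0.0, hi, xtol=1e-15, rtol=1e-15)
    return x / b


@pytest.fixture
def fb_oracle():
    return mass_action_fraction_bound


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
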