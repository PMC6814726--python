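import math

import pytest

from sqmsim import DecisionNetworkParams, ModelParams


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def net() -> DecisionNetworkParams:
    return DecisionNetworkParams()


def euler_integrate(signal, tau: float, step: float = 1e-8) -> float:
    """Forward-Euler oracle for the leaky integrator.

    Computes the exact value the explicit Euler recurrence
    E_{k+1} = E_k*(1 - h/tau) + v*h would reach, segment by segment,
    using the geometric-series closed form of that recurrence (the
    result is bit-for-bit the Euler iterate, just without the loop).
    """
    E = 0.0
    for t0, t1, v in signal.segments():
        dur = (t1 - t0) / 1000.0
        m = int(round(dur / step))
        a = 1.0 - step / tau
        am = a**m
        E = E * am + v * tau * (1.0 - am)
    return E
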