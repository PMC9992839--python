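import numpy as np
import pytest

from titinmech.mech_model import TABLE1_PARAMS, ForceStepProtocol, TitinMechParams


def ideal_protocol(
    delta_T: float,
    duration: float = 0.25,
    t_step: float = 5e-3,
    dt: float = 1e-5,
) -> ForceStepProtocol:
    """Idealized step: the force ramps over exactly one sample, so the
    discrete trace is exactly the piecewise-linear forcing the integrator
    assumes and the step half-time sits at the ramp midpoint."""
    return ForceStepProtocol(
        delta_T=delta_T, rise_time=dt, t_step=t_step, duration=duration, dt=dt
    )


@pytest.fixture(scope="session")
def table1() -> dict[float, TitinMechParams]:
    return TABLE1_PARAMS


@pytest.fixture(scope="session")
def off_params() -> TitinMechParams:
    """Default OFF-state parameters: fluidity 1e3 nm/(s pN) at 2.7 um,
    contour length 3.15 um, PEVK compliance 0.65 nm/pN."""
    return TitinMechParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(12345))
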