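import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tvcoupling as tv

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SQRT2 = math.sqrt(2.0)

#: detuning and sine amplitude of the main intermittency configuration
OMEGA = 1.08
AMPLITUDE = 1.55  # sqrt(2) * alpha
ALPHA = AMPLITUDE / SQRT2


@pytest.fixture(scope="session")
def main_schedule() -> tv.ModulationSchedule:
    """The reference periodic schedule: eps=0.01, k=100, T=1000, T1=490, T2=990."""
    return tv.ModulationSchedule(alpha=ALPHA, eps=0.01, kfast=100.0,
                                 T=1000.0, T1=490.0, T2=990.0)


@pytest.fixture(scope="session")
def main_params(main_schedule) -> tv.SystemParams:
    return tv.SystemParams(schedule=main_schedule, Omega=OMEGA)


@pytest.fixture(scope="session")
def main_run(main_params) -> tv.PhaseTrack:
    """The full 5000 s phase-difference simulation at h = 0.001 s."""
    return tv.simulate_psi(main_params, 5000.0, 0.001)


def constant_coupling_pair(c1: float, c2: float, noise_sd: float = 0.0,
                           seed: int = 0, duration: float = 120.0,
                           h: float = 0.001):
    """Two-phase synthetic with a frozen diffusive coupling (c1, c2)."""
    amp = math.hypot(c1, c2)
    sched = tv.ConstantRateSchedule(alpha=amp / SQRT2, rate=0.0,
                                    phi0=math.atan2(c2, c1))
    params = tv.SystemParams(schedule=sched, omega1=5.01, omega2=3.93,
                             noise_sd=noise_sd, seed=seed)
    return tv.simulate_full(params, duration, h)
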