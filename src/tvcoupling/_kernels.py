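"""Inner integration loops.

These are sequential scalar recursions (fixed-step RK4 and Euler-Maruyama),
so they are written as tight loops and compiled with numba when it is
available; without numba the same functions run as plain Python, which is
correct but much slower for long runs.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=False)
def rk4_psi(psi0: float, Omega: float, K: float, h: float,
            phi_half: np.ndarray) -> np.ndarray:
    """Integrate dpsi/dt = Omega - K sin(psi + phi(t)).

    `phi_half` holds phi on the half-step grid t0, t0+h/2, t0+h, ... so that
    stage times of step i are indices 2i, 2i+1, 2i+2.
    """
    n = (phi_half.size - 1) // 2
    out = np.empty(n + 1)
    out[0] = psi0
    for i in range(n):
        p = out[i]
        j = 2 * i
        k1 = Omega - K * math.sin(p + phi_half[j])
        k2 = Omega - K * math.sin(p + 0.5 * h * k1 + phi_half[j + 1])
        k3 = Omega - K * math.sin(p + 0.5 * h * k2 + phi_half[j + 1])
        k4 = Omega - K * math.sin(p + h * k3 + phi_half[j + 2])
        out[i + 1] = p + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return out


@njit(cache=False)
def rk4_eta(eta0: float, Omega: float, K: float, h: float,
            rate_half: np.ndarray) -> np.ndarray:
    """Integrate deta/dt = Omega + phidot(t) - K sin(eta), phidot pretabulated."""
    n = (rate_half.size - 1) // 2
    out = np.empty(n + 1)
    out[0] = eta0
    for i in range(n):
        e = out[i]
        j = 2 * i
        k1 = Omega + rate_half[j] - K * math.sin(e)
        k2 = Omega + rate_half[j + 1] - K * math.sin(e + 0.5 * h * k1)
        k3 = Omega + rate_half[j + 1] - K * math.sin(e + 0.5 * h * k2)
        k4 = Omega + rate_half[j + 2] - K * math.sin(e + h * k3)
        out[i + 1] = e + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return out


@njit(cache=False)
def rk4_phi2(phi2_0: float, omega2: float, h: float, phi1_half: np.ndarray,
             c1_half: np.ndarray, c2_half: np.ndarray) -> np.ndarray:
    """Integrate the driven phase dphi2/dt = omega2 + q_t(phi1(t), phi2)."""
    n = (phi1_half.size - 1) // 2
    out = np.empty(n + 1)
    out[0] = phi2_0
    for i in range(n):
        p = out[i]
        j = 2 * i
        d = phi1_half[j] - p
        k1 = omega2 + c1_half[j] * math.sin(d) + c2_half[j] * math.cos(d)
        d = phi1_half[j + 1] - (p + 0.5 * h * k1)
        k2 = omega2 + c1_half[j + 1] * math.sin(d) + c2_half[j + 1] * math.cos(d)
        d = phi1_half[j + 1] - (p + 0.5 * h * k2)
        k3 = omega2 + c1_half[j + 1] * math.sin(d) + c2_half[j + 1] * math.cos(d)
        d = phi1_half[j + 2] - (p + h * k3)
        k4 = omega2 + c1_half[j + 2] * math.sin(d) + c2_half[j + 2] * math.cos(d)
        out[i + 1] = p + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return out


@njit(cache=False)
def em_pair(phi1_0: float, phi2_0: float, omega1: float, omega2: float,
            h: float, c1: np.ndarray, c2: np.ndarray,
            dW1: np.ndarray, dW2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama step of the noisy pair; dW* are pre-scaled increments."""
    n = c1.size
    p1 = np.empty(n + 1)
    p2 = np.empty(n + 1)
    p1[0] = phi1_0
    p2[0] = phi2_0
    for i in range(n):
        d = p1[i] - p2[i]
        p1[i + 1] = p1[i] + h * omega1 + dW1[i]
        p2[i + 1] = (p2[i]
                     + h * (omega2 + c1[i] * math.sin(d) + c2[i] * math.cos(d))
                     + dW2[i])
    return p1, p2
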