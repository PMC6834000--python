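"""Time-variation law of the coupling parameters at constant net strength.

The driven oscillator feels a diffusive coupling whose parameters rotate,

    c1(t) = sqrt(2) * alpha * cos(phi(t)),   c2(t) = sqrt(2) * alpha * sin(phi(t)),

so that sqrt(c1^2 + c2^2) = sqrt(2)*alpha at every instant and the net
coupling strength (the torus L2 norm) stays pinned at alpha while the
*form* of the coupling function changes.  The rotation angle is

    phi(t) = f(t) * t,

with f a T-periodic piecewise-linear rate: a slow plateau at `eps` on
[0, T1], a linear ramp up to `kfast` on [T1, T/2], a fast plateau on
[T/2, T2], and a ramp back down on [T2, T].  Slow phases of phi produce
phase locking of the two oscillators; fast winding of phi averages the
coupling away and produces phase slips.

Note that the raw (non-reduced) time multiplies f: only the rate f itself
is T-periodic, so later periods wind phi further even on slow plateaus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ConfigurationError
from .torus import FourierCoupling

__all__ = ["CouplingSchedule", "ModulationSchedule", "ConstantRateSchedule"]

SQRT2 = math.sqrt(2.0)


def _check_nonnegative_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time is not in the schedule's domain")
    return t


def _maybe_scalar(x: np.ndarray):
    return float(x) if x.ndim == 0 else x


class CouplingSchedule:
    """Common surface of modulation laws: rate f(t), angle phi(t), (c1, c2)."""

    alpha: float

    def f(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def phase_shift(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def phase_shift_rate(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def coupling_params(self, t):
        """(c1, c2) = sqrt(2)*alpha*(cos phi, sin phi); broadcasts over t."""
        phi = self.phase_shift(t)
        amp = SQRT2 * self.alpha
        c1 = amp * np.cos(phi)
        c2 = amp * np.sin(phi)
        if np.ndim(phi) == 0:
            return float(c1), float(c2)
        return c1, c2

    def coupling_at(self, t: float) -> FourierCoupling:
        """The frozen diffusive coupling function at time t."""
        c1, c2 = self.coupling_params(float(t))
        return FourierCoupling.diffusive(c1, c2)


@dataclass(frozen=True)
class ModulationSchedule(CouplingSchedule):
    """Piecewise-linear periodic rate f(t) with plateaus `eps` and `kfast`.

    Parameters
    ----------
    alpha : float
        Net coupling strength, 1/s; the L2 norm of the induced coupling.
    eps : float
        Slow-plateau rate, rad/s (>= 0).
    kfast : float
        Fast-plateau rate, rad/s (> eps).
    T, T1, T2 : float
        Period and plateau breakpoints, s, with 0 < T1 < T/2 < T2 < T.
    """

    alpha: float
    eps: float
    kfast: float
    T: float
    T1: float
    T2: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ConfigurationError("alpha must be positive")
        if not (self.kfast > self.eps >= 0):
            raise ConfigurationError("need kfast > eps >= 0")
        if not (0 < self.T1 < self.T / 2 < self.T2 < self.T):
            raise ConfigurationError("need 0 < T1 < T/2 < T2 < T")

    # -- the piecewise rate ------------------------------------------------

    def _reduced(self, t: np.ndarray) -> np.ndarray:
        return t - self.T * np.floor(t / self.T)

    def f(self, t):
        """The T-periodic rate, evaluated branch-by-branch in printed order."""
        t = _check_nonnegative_time(t)
        tm = self._reduced(t)
        eps, k, T, T1, T2 = self.eps, self.kfast, self.T, self.T1, self.T2
        up = (eps * (T / 2 - tm) + k * (tm - T1)) / (T / 2 - T1)
        down = (k * (T - tm) + eps * (tm - T2)) / (T - T2)
        out = np.select([tm <= T1, tm <= T / 2, tm <= T2], [eps, up, k], default=down)
        return _maybe_scalar(out)

    def _fprime(self, tm: np.ndarray) -> np.ndarray:
        """One-sided derivative of f, using the same branch order as `f`."""
        eps, k, T, T1, T2 = self.eps, self.kfast, self.T, self.T1, self.T2
        slope_up = (k - eps) / (T / 2 - T1)
        slope_down = (eps - k) / (T - T2)
        return np.select([tm <= T1, tm <= T / 2, tm <= T2],
                         [0.0, slope_up, 0.0], default=slope_down)

    # -- the winding angle -------------------------------------------------

    def phase_shift(self, t):
        """phi(t) = f(t) * t, with the *raw* time in the product."""
        t = _check_nonnegative_time(t)
        return _maybe_scalar(np.asarray(self.f(t)) * t)

    def phase_shift_rate(self, t):
        """d/dt [f(t) t] = f(t) + f'(t) t, per branch; one-sided at corners."""
        t = _check_nonnegative_time(t)
        tm = self._reduced(t)
        out = np.asarray(self.f(t)) + self._fprime(tm) * t
        return _maybe_scalar(out)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "eps": self.eps, "kfast": self.kfast,
                "T": self.T, "T1": self.T1, "T2": self.T2}

    @classmethod
    def from_dict(cls, doc) -> "ModulationSchedule":
        return cls(**{key: float(doc[key]) for key in
                      ("alpha", "eps", "kfast", "T", "T1", "T2")})

    @classmethod
    def from_yaml(cls, path) -> "ModulationSchedule":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class ConstantRateSchedule(CouplingSchedule):
    """Uniform winding phi(t) = phi0 + rate * t (frozen coupling when rate = 0).

    This is the autonomous comparison case: `rate = 0` freezes the coupling
    function, while a constant positive rate realises pure fast winding.
    """

    alpha: float
    rate: float = 0.0
    phi0: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError("alpha must be non-negative")

    def f(self, t):
        t = _check_nonnegative_time(t)
        return _maybe_scalar(np.full_like(t, self.rate, dtype=float))

    def phase_shift(self, t):
        t = _check_nonnegative_time(t)
        return _maybe_scalar(self.phi0 + self.rate * t)

    def phase_shift_rate(self, t):
        t = _check_nonnegative_time(t)
        return _maybe_scalar(np.full_like(t, self.rate, dtype=float))

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "rate": self.rate, "phi0": self.phi0}
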