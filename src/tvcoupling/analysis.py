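"""Synchronization epochs, frozen fixed points and averaging certificates.

Segmentation labels a phase-difference track as *locked* (sliding-window
mean slope below a threshold) or *slipping*, then absorbs intervals shorter
than a minimum duration into their neighbours, so the result is an ordered,
alternating tiling of the analysed span.

The certificate operations turn the two analytical statements about the
driven Adler equation into empirical checks on trajectories:

* *slow driving*: if the winding rate |dphi/dt| stays below a computable
  tolerance eps0, then eta = psi + phi enters the eps~/2-ball around the
  stable frozen fixed point eta* = arcsin(Omega/(sqrt(2)*alpha)) within a
  computable transient T0 and remains inside it;
* *fast winding*: if phi winds at a rate above K1 (with bounded curvature
  controlled by K2), then psi drifts at the detuning Omega up to the
  explicit bounds kappa0(K1) + kappa(K1, K2) * s, with

      kappa0 = 2*sqrt(2)*pi*alpha / K1,
      kappa  = sqrt(2)*alpha * ( 2*pi*(|Omega| + sqrt(2)*alpha)/K1
                                 + (2*pi^2/K2^2) * (1 - 2*pi/K2^2)^-2 ).

These are certificates on simulated trajectories, not proofs: bound
comparisons carry a 1e-9 absolute slack to absorb integrator error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .errors import PreconditionError
from .modulation import SQRT2, ConstantRateSchedule
from .simulate import DEFAULT_STEP, PhaseTrack, SystemParams, simulate_psi

__all__ = [
    "FrozenFixedPoints", "frozen_fixed_points",
    "EpochSegmentation", "segment_epochs", "drift_rate",
    "AveragingBounds", "averaging_bounds",
    "FastDriftReport", "certify_fast_drift",
    "SlowContainmentReport", "slow_drive_tolerance", "certify_slow_containment",
]

BOUND_SLACK = 1e-9  # absolute slack when comparing trajectories to bounds


# ---------------------------------------------------------------------------
# Frozen (autonomous) fixed points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrozenFixedPoints:
    """Stable / unstable rest angles of deta/dt = Omega - sqrt(2)*alpha*sin(eta)."""

    eta_star: float
    eta_star2: float


def frozen_fixed_points(Omega: float, alpha: float) -> FrozenFixedPoints:
    """Fixed points of the frozen phase-difference equation.

    Requires sqrt(2)*alpha > |Omega| (the locking condition).  The stable
    point is eta* = arcsin(Omega/(sqrt(2)*alpha)) on the [-pi/2, pi/2]
    branch, where the restoring derivative -sqrt(2)*alpha*cos(eta*) is
    negative; the unstable point is pi - eta*.
    """
    K = SQRT2 * alpha
    if not K > abs(Omega):
        raise PreconditionError(
            f"no fixed points: need sqrt(2)*alpha > |Omega| (got {K:g} <= {abs(Omega):g})")
    eta_star = math.asin(Omega / K)
    assert -K * math.cos(eta_star) < 0  # stability of the arcsin branch
    return FrozenFixedPoints(eta_star, math.pi - eta_star)


# ---------------------------------------------------------------------------
# Epoch segmentation
# ---------------------------------------------------------------------------

@dataclass
class EpochSegmentation:
    """Ordered alternating (start, end, label) intervals tiling a track."""

    intervals: list[tuple[float, float, str]]
    params: dict = field(default_factory=dict)

    def _of(self, label: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, lab in self.intervals if lab == label]

    @property
    def locked(self) -> list[tuple[float, float]]:
        return self._of("locked")

    @property
    def slipping(self) -> list[tuple[float, float]]:
        return self._of("slipping")

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "intervals": [{"start": a, "end": b, "label": lab}
                          for a, b, lab in self.intervals],
        }


def _sliding_slope(values: np.ndarray, h: float, window: float) -> np.ndarray:
    """Centred finite-difference slope over +-window/2, clamped at the edges."""
    n = values.size
    half = max(int(round(window / h)) // 2, 1)
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n - 1)
    hi = np.clip(idx + half, 0, n - 1)
    return (values[hi] - values[lo]) / ((hi - lo) * h)


def _runs(mask: np.ndarray) -> list[list]:
    """Run-length encode a boolean array as [start, stop, flag] (stop exclusive)."""
    edges = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [mask.size]))
    return [[int(a), int(b), bool(mask[a])]
            for a, b in zip(bounds[:-1], bounds[1:])]


def segment_epochs(track: PhaseTrack, window: float = 10.0,
                   slope_threshold: float = 0.108,
                   min_duration: float = 20.0) -> EpochSegmentation:
    """Label a phase-difference track into locked and slipping epochs.

    A sample is locked when the sliding-window mean |dpsi/dt| is below
    ``slope_threshold``; runs shorter than ``min_duration`` are then merged
    into their neighbours (shortest first, earliest on ties), so adjacent
    intervals always carry different labels.  Deterministic, idempotent and
    invariant under adding a constant to the track.
    """
    if window <= track.h:
        raise ValueError("detection window must exceed the sampling step")
    if track.h * (track.n - 1) <= window:
        raise ValueError("track must be longer than the detection window")
    slopes = _sliding_slope(track.values, track.h, window)
    locked = np.abs(slopes) < slope_threshold
    runs = _runs(locked)
    min_samples = min_duration / track.h
    while len(runs) > 1:
        lengths = [b - a for a, b, _ in runs]
        shortest = min(range(len(runs)), key=lambda i: (lengths[i], i))
        if lengths[shortest] >= min_samples:
            break
        a, b, _ = runs.pop(shortest)
        if shortest > 0:
            runs[shortest - 1][1] = b
            if shortest < len(runs):  # neighbours now share a label: fuse
                runs[shortest - 1][1] = runs[shortest][1]
                runs.pop(shortest)
        else:
            runs[0][0] = a
    t0, h = track.t0, track.h
    intervals = [(t0 + h * a, t0 + h * b if b < track.n else track.t_end,
                  "locked" if flag else "slipping") for a, b, flag in runs]
    return EpochSegmentation(intervals, params={
        "window": window, "slope_threshold": slope_threshold,
        "min_duration": min_duration})


def drift_rate(track: PhaseTrack, t_start: float, t_end: float) -> float:
    """Least-squares slope of the track over [t_start, t_end], rad/s."""
    sub = track.window(t_start, t_end)
    t = sub.times - sub.t0
    return float(np.polyfit(t, sub.values, 1)[0])


# ---------------------------------------------------------------------------
# Fast-winding averaging bounds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AveragingBounds:
    """Explicit drift-at-Omega bounds for fast winding above rate K1."""

    K1: float
    K2: float
    kappa0: float
    kappa: float


def averaging_bounds(Omega: float, alpha: float, K1: float,
                     K2: float = math.inf) -> AveragingBounds:
    """The constants bounding |psi(s) - psi(0) - Omega*s| <= kappa0 + kappa*s.

    ``K1`` is the minimum winding rate and ``K2`` bounds the relative
    curvature of phi; for linear winding (phi'' = 0) the K2 condition is
    vacuous and ``K2 = inf`` drops its term.  Both constants shrink as the
    winding gets faster.
    """
    if not K1 > 0:
        raise PreconditionError("K1 must be positive")
    if not K2 > math.sqrt(2 * math.pi):
        raise PreconditionError("K2 must exceed sqrt(2*pi) for a positive bound")
    K = SQRT2 * alpha
    kappa0 = 2 * SQRT2 * math.pi * alpha / K1
    if math.isinf(K2):
        curvature_term = 0.0
    else:
        curvature_term = (2 * math.pi ** 2 / K2 ** 2) * (1 - 2 * math.pi / K2 ** 2) ** -2
    kappa = K * (2 * math.pi * (abs(Omega) + K) / K1 + curvature_term)
    return AveragingBounds(K1, K2, kappa0, kappa)


@dataclass(frozen=True)
class FastDriftReport:
    """Empirical check of the fast-winding drift bound on one trajectory."""

    bounds: AveragingBounds
    max_deviation: float
    margin: float
    passed: bool
    duration: float
    h: float


def certify_fast_drift(params: SystemParams, duration: float,
                       h: float | None = None, K1: float | None = None,
                       K2: float = math.inf) -> FastDriftReport:
    """Simulate psi under uniform fast winding and compare to the bound.

    Requires a :class:`ConstantRateSchedule` with rate k >= K1 > 0 (linear
    winding, so the curvature condition is vacuous).  The report's margin is
    ``max_s |psi(s) - psi(0) - Omega*s| - (kappa0 + kappa*s)``, which the
    averaging argument guarantees to be <= 0.
    """
    sched = params.schedule
    if not isinstance(sched, ConstantRateSchedule) or sched.rate <= 0:
        raise PreconditionError("fast-drift certificate needs a constant-rate "
                                "schedule with positive rate")
    if K1 is None:
        K1 = sched.rate
    if sched.rate < K1:
        raise PreconditionError("winding rate must be at least K1")
    bounds = averaging_bounds(params.Omega, sched.alpha, K1, K2)
    if h is None:
        # resolve the winding: at least ~60 steps per 2*pi turn
        h = min(DEFAULT_STEP, 0.1 / sched.rate)
    track = simulate_psi(params, duration, h)
    s = track.times
    deviation = np.abs(track.values - track.values[0] - params.Omega * s)
    margin = float(np.max(deviation - (bounds.kappa0 + bounds.kappa * s)))
    return FastDriftReport(bounds, float(deviation.max()), margin,
                           margin <= BOUND_SLACK, duration, h)


# ---------------------------------------------------------------------------
# Slow-driving containment
# ---------------------------------------------------------------------------

def _wrap(x: float) -> float:
    return (x + math.pi) % (2 * math.pi) - math.pi


def slow_drive_tolerance(Omega: float, alpha: float, eta0: float,
                         eps_tilde: float, safety: float = 0.9
                         ) -> tuple[float, float]:
    """Admissible winding rate eps0 and transient T0 for ball containment.

    Follows the constructive recipe: with F(eta) = Omega - sqrt(2)*alpha*
    sin(eta), pick eps0 below min(|F(eta0)|, F(eta* - eps~/2),
    -F(eta* + eps~/2)) (scaled by ``safety``) and integrate the worst-case
    travel time T0 = int d(eta) / (|F(eta)| - eps0) from eta0 to the edge of
    the eps~/2-ball around the stable point eta*.
    """
    fp = frozen_fixed_points(Omega, alpha)
    K = SQRT2 * alpha

    def F(eta: float) -> float:
        return Omega - K * math.sin(eta)

    half = eps_tilde / 2.0
    if not half > 0:
        raise ValueError("eps_tilde must be positive")
    if abs(_wrap(eta0 - fp.eta_star2)) < 1e-12:
        raise PreconditionError("eta0 coincides with the unstable fixed point")
    if not half < abs(math.pi / 2 - fp.eta_star):
        raise PreconditionError("eps_tilde/2 must stay within the monotone arc "
                                "around eta*")
    d_eta0 = abs(_wrap(eta0 - fp.eta_star))
    if d_eta0 <= half:
        # already inside the ball: the edge conditions alone trap the orbit
        eps0 = safety * min(F(fp.eta_star - half), -F(fp.eta_star + half))
        return eps0, 0.0
    gap = min(abs(F(eta0)), F(fp.eta_star - half), -F(fp.eta_star + half))
    if not gap > 0:
        raise PreconditionError("no admissible winding rate for this eta0/eps_tilde")
    eps0 = safety * gap
    # travel from eta0 to the ball edge along the flow direction of F,
    # working with the representative of eta0 nearest to eta*
    e0 = fp.eta_star + _wrap(eta0 - fp.eta_star)
    if F(e0) > 0:
        target = fp.eta_star - half
        if target < e0:
            target += 2 * math.pi
        lo, hi = e0, target
    else:
        target = fp.eta_star + half
        if target > e0:
            target -= 2 * math.pi
        lo, hi = target, e0
    T0, _ = quad(lambda e: 1.0 / (abs(F(e)) - eps0), lo, hi, limit=200)
    return eps0, float(T0)


@dataclass(frozen=True)
class SlowContainmentReport:
    """Empirical check that eta = psi + phi stays near eta* under slow driving."""

    eta_star: float
    eps0: float
    T0: float
    eps_tilde: float
    first_violation: float | None
    max_deviation_after_T0: float
    passed: bool


def certify_slow_containment(params: SystemParams, eps_tilde: float,
                             duration: float | None = None,
                             h: float = DEFAULT_STEP,
                             safety: float = 0.9) -> SlowContainmentReport:
    """Simulate psi under slow winding and verify ball containment.

    Computes (eps0, T0) from :func:`slow_drive_tolerance` for the initial
    angle eta0 = psi0 + phi(0), requires the schedule's winding rate to
    satisfy |dphi/dt| <= eps0 throughout the run, then checks that
    psi(s) + phi(s) lies within eps_tilde/2 of eta* for every s > T0.
    """
    sched = params.schedule
    eta0 = params.psi0 + float(sched.phase_shift(0.0))
    eps0, T0 = slow_drive_tolerance(params.Omega, sched.alpha, eta0,
                                    eps_tilde, safety)
    if duration is None:
        duration = T0 + 100.0
    probe = np.linspace(0.0, duration, 4097)
    max_rate = float(np.max(np.abs(sched.phase_shift_rate(probe))))
    if max_rate > eps0 + BOUND_SLACK:
        raise PreconditionError(
            f"schedule winds at up to {max_rate:g} rad/s, above eps0 = {eps0:g}")
    track = simulate_psi(params, duration, h)
    t = track.times
    eta = track.values + np.asarray(sched.phase_shift(t))
    fp = frozen_fixed_points(params.Omega, sched.alpha)
    dev = np.abs(np.mod(eta - fp.eta_star + np.pi, 2 * np.pi) - np.pi)
    after = t > T0
    violating = after & (dev > eps_tilde / 2.0 + BOUND_SLACK)
    first = float(t[violating][0]) if violating.any() else None
    max_dev = float(dev[after].max()) if after.any() else 0.0
    return SlowContainmentReport(fp.eta_star, eps0, T0, eps_tilde, first,
                                 max_dev, first is None)
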