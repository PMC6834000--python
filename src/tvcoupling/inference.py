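"""Windowed inference of time-varying coupling functions from phase pairs.

Within each sliding window the driven phase is modelled as

    dphi2/dt = omega2 + sum_(k,l) [ a_kl cos(k phi1 + l phi2)
                                    + b_kl sin(k phi1 + l phi2) ] + noise,

with harmonics up to a chosen order (default 2) on the 2-torus.  Phase
velocities come from central finite differences (one-sided at window
edges), optionally decimated to a coarser regression step, and the
coefficients are estimated by Bayesian linear regression: a zero-mean
Gaussian prior with standard deviation ``prior_sd`` on every coupling
coefficient and a flat prior on omega2.  The per-window noise scale is
estimated from ordinary-least-squares residuals, so the whole procedure is
closed-form and deterministic.

Each window yields a :class:`~tvcoupling.torus.FourierCoupling`, from which
the two summary series of the coupling are derived: the net coupling
strength eps(t) (the torus L2 norm per window) and the similarity index
rho(t) (cosine similarity between the window's coupling and the
coefficient-wise time-averaged coupling).

Windows must be short against the timescale on which the true coupling
rotates, or the rotation averages out inside the window and the inferred
strength collapses; and windows in which the phases stay strictly locked
explore only a short arc of the torus diagonal, which leaves the curvature
of the coupling along that arc (hence part of its norm) weakly identified
unless dynamical noise widens the exploration.  See the methods note.

An optional prior-carryover mode propagates each window's posterior to the
next window as a prior with inflated covariance (a random-walk model of
coefficient drift), which stabilises weakly identified windows at the cost
of temporal smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import PreconditionError
from .simulate import PhaseTrack
from .torus import FourierCoupling, mean_coupling

__all__ = ["WindowedCouplingSeries", "WindowedCouplingInference",
           "infer_windowed", "strength_series", "similarity_series",
           "fourier_pairs"]


def fourier_pairs(order: int) -> list[tuple[int, int]]:
    """Canonical harmonic pairs (k, l), |k|,|l| <= order, one per +-pair."""
    pairs = []
    for k in range(0, order + 1):
        for l in range(-order, order + 1):
            if k == 0 and l <= 0:
                continue
            pairs.append((k, l))
    return pairs


def _design(phi1: np.ndarray, phi2: np.ndarray,
            pairs: list[tuple[int, int]]) -> np.ndarray:
    X = np.empty((phi1.size, 1 + 2 * len(pairs)))
    X[:, 0] = 1.0
    for j, (k, l) in enumerate(pairs):
        theta = k * phi1 + l * phi2
        X[:, 1 + 2 * j] = np.cos(theta)
        X[:, 2 + 2 * j] = np.sin(theta)
    return X


@dataclass
class WindowedCouplingSeries:
    """Per-window inferred couplings with the derived eps(t), rho(t) series."""

    window_centers: np.ndarray
    couplings: list[FourierCoupling]
    omega2: np.ndarray
    noise_sd: np.ndarray
    strength: np.ndarray
    similarity: np.ndarray
    mean: FourierCoupling
    params: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.couplings)

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame({
            "window_center": self.window_centers,
            "omega2_hat": self.omega2,
            "noise_sd_hat": self.noise_sd,
            "eps": self.strength,
            "rho": self.similarity,
        })
        pairs = sorted({kl for q in self.couplings for kl in q.coeffs})
        for k, l in pairs:
            frame[f"cos_{k}_{l}"] = [q.coefficient(k, l)[0] for q in self.couplings]
            frame[f"sin_{k}_{l}"] = [q.coefficient(k, l)[1] for q in self.couplings]
        return frame


def strength_series(series: WindowedCouplingSeries) -> np.ndarray:
    """eps(t): the net coupling strength of each window's coupling."""
    return np.array([q.norm() for q in series.couplings])


def similarity_series(series: WindowedCouplingSeries) -> np.ndarray:
    """rho(t): cosine similarity of each window to the time-averaged coupling.

    Raises :class:`~tvcoupling.errors.ZeroNormError` when the mean coupling
    vanishes; windows whose own coupling has zero norm yield NaN.
    """
    if series.n_windows < 2:
        raise PreconditionError("similarity series needs at least two windows")
    ref = series.mean
    if ref.norm() == 0.0:
        from .errors import ZeroNormError

        raise ZeroNormError("time-averaged coupling has zero norm")
    out = np.empty(series.n_windows)
    for i, q in enumerate(series.couplings):
        out[i] = q.similarity(ref) if q.norm() > 0.0 else np.nan
    return out


class WindowedCouplingInference:
    """Sliding-window estimator of the coupling function of a driven phase.

    Parameters
    ----------
    window, stride : float
        Window length and stride, s.
    order : int
        Maximum Fourier harmonic on the torus (1 or 2).
    prior_sd : float
        Gaussian prior standard deviation on each coupling coefficient,
        rad/s; omega2 carries a flat prior.
    regression_step : float
        Target sampling step for the regression, s; the tracks are decimated
        to roughly this step before differencing to keep the cost modest.
    carryover_diffusion : float or None
        If set, each window's posterior becomes the next window's prior with
        covariance inflated by ``carryover_diffusion**2 * stride`` per
        coefficient (random-walk drift model); None keeps windows
        independent.

    After :meth:`fit`, the fitted attributes ``series_``,
    ``window_centers_``, ``couplings_``, ``omega2_``, ``noise_sd_``,
    ``strength_``, ``similarity_`` and ``mean_coupling_`` are available.
    """

    def __init__(self, window: float = 50.0, stride: float = 25.0,
                 order: int = 2, prior_sd: float = 2.0,
                 regression_step: float = 0.01,
                 carryover_diffusion: float | None = None) -> None:
        self.window = window
        self.stride = stride
        self.order = order
        self.prior_sd = prior_sd
        self.regression_step = regression_step
        self.carryover_diffusion = carryover_diffusion

    # -- sklearn-style plumbing -------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {"window": self.window, "stride": self.stride,
                "order": self.order, "prior_sd": self.prior_sd,
                "regression_step": self.regression_step,
                "carryover_diffusion": self.carryover_diffusion}

    def set_params(self, **params) -> "WindowedCouplingInference":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------

    def fit(self, phi1: PhaseTrack, phi2: PhaseTrack) -> "WindowedCouplingInference":
        if self.order not in (1, 2):
            raise ValueError("order must be 1 or 2")
        if (phi1.h != phi2.h or phi1.t0 != phi2.t0 or phi1.n != phi2.n):
            raise PreconditionError("phase tracks must share their sampling grid")
        h = phi1.h
        if self.window < 20 * h:
            raise PreconditionError("window must cover at least 20 samples")
        duration = h * (phi1.n - 1)
        if self.window > duration:
            raise PreconditionError("window exceeds the track")

        decim = max(1, int(round(self.regression_step / h)))
        p1 = phi1.values[::decim]
        p2 = phi2.values[::decim]
        dt = h * decim
        window_samples = int(round(self.window / dt))
        stride_samples = max(1, int(round(self.stride / dt)))
        n_windows = int(np.floor((duration - self.window) / self.stride)) + 1

        pairs = fourier_pairs(self.order)
        n_coef = 2 * len(pairs)
        prior_prec = np.zeros(1 + n_coef)
        prior_prec[1:] = 1.0 / self.prior_sd ** 2

        carry = self.carryover_diffusion
        prior_mean = np.zeros(1 + n_coef)
        prior_cov = None
        if carry is not None:
            # flat prior on omega2 approximated by a huge variance
            prior_cov = np.diag(
                np.concatenate(([1e8], np.full(n_coef, self.prior_sd ** 2))))

        centers = np.empty(n_windows)
        couplings: list[FourierCoupling] = []
        omega2 = np.empty(n_windows)
        noise = np.empty(n_windows)

        for w in range(n_windows):
            i0 = int(round(w * stride_samples))
            i1 = min(i0 + window_samples, p1.size - 1)
            sl = slice(i0, i1 + 1)
            y = np.gradient(p2[sl], dt)
            X = _design(p1[sl], p2[sl], pairs)
            m, p = X.shape
            beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta_ls
            sigma2 = float(resid @ resid) / max(m - p, 1) if m > p else 0.0

            if carry is None:
                if sigma2 > 0:
                    aug = np.sqrt(sigma2) * np.diag(np.sqrt(prior_prec))
                    Xa = np.vstack([X, aug[1:]])  # flat prior row for omega2 dropped
                    ya = np.concatenate([y, np.zeros(n_coef)])
                    beta, *_ = np.linalg.lstsq(Xa, ya, rcond=None)
                else:
                    beta = beta_ls
            else:
                s2 = max(sigma2, 1e-12)
                prior_precision = np.linalg.inv(prior_cov)
                post_precision = prior_precision + (X.T @ X) / s2
                rhs = prior_precision @ prior_mean + (X.T @ y) / s2
                beta = np.linalg.solve(post_precision, rhs)
                post_cov = np.linalg.inv(post_precision)
                prior_cov = post_cov + np.eye(p) * (carry ** 2 * self.stride)
                prior_mean = beta

            centers[w] = phi1.t0 + w * self.stride + self.window / 2.0
            omega2[w] = beta[0]
            coeffs = {pairs[j]: (beta[1 + 2 * j], beta[2 + 2 * j])
                      for j in range(len(pairs))}
            couplings.append(FourierCoupling(coeffs, constant=0.0, order=self.order))
            noise[w] = np.sqrt(max(sigma2, 0.0) * 2.0 * dt)

        mean = mean_coupling(couplings)
        series = WindowedCouplingSeries(
            centers, couplings, omega2, noise,
            strength=np.array([q.norm() for q in couplings]),
            similarity=np.full(n_windows, np.nan),
            mean=mean,
            params=self.get_params(),
        )
        if n_windows >= 2 and mean.norm() > 0.0:
            series.similarity = similarity_series(series)
        self.series_ = series
        self.window_centers_ = series.window_centers
        self.couplings_ = series.couplings
        self.omega2_ = series.omega2
        self.noise_sd_ = series.noise_sd
        self.strength_ = series.strength
        self.similarity_ = series.similarity
        self.mean_coupling_ = series.mean
        return self


def infer_windowed(phi1: PhaseTrack, phi2: PhaseTrack, window: float = 50.0,
                   stride: float = 25.0, order: int = 2, prior_sd: float = 2.0,
                   regression_step: float = 0.01,
                   carryover_diffusion: float | None = None
                   ) -> WindowedCouplingSeries:
    """Functional wrapper over :class:`WindowedCouplingInference`."""
    est = WindowedCouplingInference(window=window, stride=stride, order=order,
                                    prior_sd=prior_sd,
                                    regression_step=regression_step,
                                    carryover_diffusion=carryover_diffusion)
    return est.fit(phi1, phi2).series_
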