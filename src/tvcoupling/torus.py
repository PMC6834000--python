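"""Coupling functions on the 2-torus.

A coupling function q(phi1, phi2) describes the influence one oscillator
exerts on the phase velocity of another.  Because phases live on the circle,
q is 2*pi-periodic in both arguments and can be represented by a finite
Fourier expansion on the torus T^2, identified with the square [-pi, pi]^2.

Two scalar summaries of a coupling function are used throughout:

* the *net coupling strength*, its L2 norm under the normalised inner
  product <f, g> = (1/4 pi^2) \\int\\int f g dphi1 dphi2, computed from the
  Fourier coefficients via Parseval's identity;
* the *similarity index*, the cosine similarity between two coupling
  functions under the same inner product, which compares their functional
  form independently of overall strength.

The workhorse special case is the diffusive coupling
``c1*sin(phi1 - phi2) + c2*cos(phi1 - phi2)``, whose norm is
``sqrt((c1^2 + c2^2)/2)``.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import ZeroNormError

__all__ = [
    "FourierCoupling",
    "evaluate",
    "parseval_norm",
    "similarity_index",
    "mean_coupling",
]

Pair = tuple[int, int]


def _canonical(k: int, l: int, a: float, b: float) -> tuple[int, int, float, float]:
    """Map the harmonic (k, l) to its canonical representative.

    cos(k x + l y) is even and sin odd under (k, l) -> (-k, -l), so every
    harmonic with k < 0, or k == 0 and l < 0, folds onto its negation with
    the sine part flipped.
    """
    if k < 0 or (k == 0 and l < 0):
        return -k, -l, a, -b
    return k, l, a, b


class FourierCoupling:
    """A 2*pi-biperiodic coupling function as a finite Fourier sum.

    Parameters
    ----------
    coeffs
        Mapping from harmonic pairs ``(k, l)`` to coefficient pairs
        ``(cos_part, sin_part)`` of ``cos(k*phi1 + l*phi2)`` and
        ``sin(k*phi1 + l*phi2)``, in rad/s.  Harmonics are canonicalised so
        that ``k > 0`` or (``k == 0`` and ``l > 0``); duplicates accumulate.
    constant
        The constant Fourier term, rad/s.
    order
        Maximum harmonic ``max(|k|, |l|)``.  Inferred from ``coeffs`` when
        omitted; must dominate every supplied harmonic when given.
    """

    def __init__(
        self,
        coeffs: Mapping[Pair, tuple[float, float]] | None = None,
        constant: float = 0.0,
        order: int | None = None,
    ) -> None:
        folded: dict[Pair, list[float]] = {}
        for (k, l), (a, b) in (coeffs or {}).items():
            k = int(k)
            l = int(l)
            if k == 0 and l == 0:
                raise ValueError("(0, 0) is the constant term; pass it as `constant`")
            ck, cl, ca, cb = _canonical(k, l, float(a), float(b))
            acc = folded.setdefault((ck, cl), [0.0, 0.0])
            acc[0] += ca
            acc[1] += cb
        self._coeffs: dict[Pair, tuple[float, float]] = {
            kl: (a, b) for kl, (a, b) in sorted(folded.items()) if a != 0.0 or b != 0.0
        }
        self.constant = float(constant)
        inferred = max((max(abs(k), abs(l)) for k, l in self._coeffs), default=0)
        if order is None:
            order = max(inferred, 1)
        order = int(order)
        if order < 1:
            raise ValueError("order must be a positive integer")
        if inferred > order:
            raise ValueError(f"harmonic exceeds declared order {order}")
        self.order = order

    # -- constructors ------------------------------------------------------

    @classmethod
    def diffusive(cls, c1: float, c2: float) -> "FourierCoupling":
        """c1*sin(phi1 - phi2) + c2*cos(phi1 - phi2), exactly order 1."""
        return cls({(1, -1): (c2, c1)}, order=1)

    # -- evaluation --------------------------------------------------------

    def __call__(self, phi1, phi2):
        """Evaluate the Fourier sum; broadcasts like numpy ufuncs."""
        phi1 = np.asarray(phi1, dtype=float)
        phi2 = np.asarray(phi2, dtype=float)
        out = np.full(np.broadcast_shapes(phi1.shape, phi2.shape), self.constant)
        for (k, l), (a, b) in self._coeffs.items():
            theta = k * phi1 + l * phi2
            if a != 0.0:
                out += a * np.cos(theta)
            if b != 0.0:
                out += b * np.sin(theta)
        if out.ndim == 0:
            return float(out)
        return out

    # -- coefficient access ------------------------------------------------

    @property
    def coeffs(self) -> dict[Pair, tuple[float, float]]:
        return dict(self._coeffs)

    def coefficient(self, k: int, l: int) -> tuple[float, float]:
        """Return (cos_part, sin_part) for harmonic (k, l), any sign convention."""
        ck, cl, sa, sb = _canonical(int(k), int(l), 1.0, 1.0)
        a, b = self._coeffs.get((ck, cl), (0.0, 0.0))
        return a * sa, b * sb

    def diffusive_params(self) -> tuple[float, float]:
        """(c1, c2) of the sin/cos(phi1 - phi2) pair (other harmonics ignored)."""
        a, b = self.coefficient(1, -1)
        return b, a

    # -- algebra -----------------------------------------------------------

    def __mul__(self, lam: float) -> "FourierCoupling":
        lam = float(lam)
        return FourierCoupling(
            {kl: (lam * a, lam * b) for kl, (a, b) in self._coeffs.items()},
            constant=lam * self.constant,
            order=self.order,
        )

    __rmul__ = __mul__

    def __neg__(self) -> "FourierCoupling":
        return self * -1.0

    def __add__(self, other: "FourierCoupling") -> "FourierCoupling":
        merged: dict[Pair, tuple[float, float]] = dict(self._coeffs)
        for kl, (a, b) in other._coeffs.items():
            pa, pb = merged.get(kl, (0.0, 0.0))
            merged[kl] = (pa + a, pb + b)
        return FourierCoupling(
            merged,
            constant=self.constant + other.constant,
            order=max(self.order, other.order),
        )

    # -- inner-product geometry -------------------------------------------

    def inner(self, other: "FourierCoupling") -> float:
        """<self, other> under (1/4 pi^2) \\int\\int f g over [-pi, pi]^2.

        Distinct harmonics are orthogonal; each non-constant harmonic has
        squared norm 1/2 and the constant has norm 1.
        """
        total = self.constant * other.constant
        for kl, (a, b) in self._coeffs.items():
            oa, ob = other._coeffs.get(kl, (0.0, 0.0))
            total += 0.5 * (a * oa + b * ob)
        return total

    def norm(self) -> float:
        """Net coupling strength: L2 norm via Parseval's identity (rad/s)."""
        return math.sqrt(max(self.inner(self), 0.0))

    def similarity(self, other: "FourierCoupling") -> float:
        """Cosine similarity in L2; +1 for positive multiples, -1 for negatives."""
        na = self.norm()
        nb = other.norm()
        if na == 0.0 or nb == 0.0:
            raise ZeroNormError("similarity index undefined for zero-norm coupling")
        return self.inner(other) / (na * nb)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "constant": self.constant,
            "coefficients": [
                {"k": k, "l": l, "cos": a, "sin": b}
                for (k, l), (a, b) in self._coeffs.items()
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FourierCoupling":
        coeffs = {
            (int(row["k"]), int(row["l"])): (float(row["cos"]), float(row["sin"]))
            for row in doc.get("coefficients", [])
        }
        return cls(coeffs, constant=float(doc.get("constant", 0.0)),
                   order=int(doc["order"]) if "order" in doc else None)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "FourierCoupling":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- export ------------------------------------------------------------

    def grid(self, n: int = 64):
        """Tabulate on an n x n grid over [-pi, pi)^2 as a tidy DataFrame."""
        import pandas as pd

        axis = -np.pi + 2 * np.pi * np.arange(n) / n
        p1, p2 = np.meshgrid(axis, axis, indexing="ij")
        return pd.DataFrame(
            {"phi1": p1.ravel(), "phi2": p2.ravel(), "value": self(p1, p2).ravel()}
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"FourierCoupling(order={self.order}, constant={self.constant!r}, "
                f"coeffs={self._coeffs!r})")


# -- functional wrappers ---------------------------------------------------

def evaluate(q: FourierCoupling, phi1, phi2):
    """Evaluate q at (phi1, phi2); 2*pi-periodic in both arguments."""
    return q(phi1, phi2)


def parseval_norm(q: FourierCoupling) -> float:
    """Net coupling strength of q (L2 norm on the torus), rad/s."""
    return q.norm()


def similarity_index(q: FourierCoupling, q_ref: FourierCoupling) -> float:
    """Cosine similarity between two coupling functions in [-1, 1]."""
    return q.similarity(q_ref)


def mean_coupling(couplings: Sequence[FourierCoupling] | Iterable[FourierCoupling]) -> FourierCoupling:
    """Coefficient-wise average of a collection of coupling functions."""
    couplings = list(couplings)
    if not couplings:
        raise ValueError("mean of an empty collection of couplings")
    acc: dict[Pair, list[float]] = {}
    const = 0.0
    for q in couplings:
        const += q.constant
        for kl, (a, b) in q._coeffs.items():
            cell = acc.setdefault(kl, [0.0, 0.0])
            cell[0] += a
            cell[1] += b
    m = len(couplings)
    return FourierCoupling(
        {kl: (a / m, b / m) for kl, (a, b) in acc.items()},
        constant=const / m,
        order=max(q.order for q in couplings),
    )
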