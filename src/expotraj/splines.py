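"""Monotone I-spline link functions and natural cubic spline time bases.

The link H(y) = eta0 + sum_k w_k^2 I_k(y) maps observed annual intensities
(right-skewed, zero-heavy) to the Gaussian latent-process scale of the
mixed model.  I-splines are running integrals of an M-spline basis, so
non-negative coefficients — enforced here by squaring — yield a monotone
non-decreasing transformation with an analytic derivative
H'(y) = sum_k w_k^2 M_k(y).

The time basis is the classic natural cubic spline construction
(truncated-power form, equivalent to R's ``ns``): cubic between the
boundary knots, linear beyond them, second derivative zero at the
boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "ISplineBasis",
    "LinkFunction",
    "TimeBasis",
    "ispline_basis",
    "transform",
    "derivative",
    "inverse_transform",
    "ncs_design",
]


class ISplineBasis:
    """I-spline / M-spline basis on a fixed knot sequence.

    ``knots`` are on the intensity scale, strictly increasing; the first and
    last are boundary knots.  ``order`` is the polynomial order of the
    I-spline pieces (default 3: quadratic, continuously differentiable,
    integrals of a piecewise-linear M-spline basis).
    """

    def __init__(self, knots, order: int = 3):
        knots = tuple(float(k) for k in knots)
        if len(knots) < 2 or np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be >= 2 strictly increasing values")
        if order < 2:
            raise ValueError("I-spline order must be >= 2")
        self.knots = knots
        self.order = order
        deg = order - 2  # degree of the M-spline (B-spline) pieces
        t = np.r_[[knots[0]] * (deg + 1), knots[1:-1], [knots[-1]] * (deg + 1)]
        self._t = t
        self._deg = deg
        self.n_basis = len(knots) - 2 + deg + 1
        # support width of each underlying B-spline; its integral is width/(deg+1)
        widths = t[deg + 1 : deg + 1 + self.n_basis] - t[: self.n_basis]
        self._norms = widths / (deg + 1)
        eye = np.eye(self.n_basis)
        self._antiderivs = [
            BSpline(t, eye[i], deg).antiderivative() for i in range(self.n_basis)
        ]

    @property
    def lo(self) -> float:
        return self.knots[0]

    @property
    def hi(self) -> float:
        return self.knots[-1]

    def clip(self, y):
        return np.clip(np.asarray(y, dtype=float), self.lo, self.hi)

    def ibasis(self, y) -> np.ndarray:
        """I-spline basis values, each in [0, 1]: all 0 at/below the first
        knot, all 1 at/above the last."""
        yc = np.atleast_1d(self.clip(y))
        out = np.empty((yc.size, self.n_basis))
        for i, a in enumerate(self._antiderivs):
            out[:, i] = a(yc) / self._norms[i]
        return np.clip(out, 0.0, 1.0)

    def mbasis(self, y) -> np.ndarray:
        """M-spline basis values (derivatives of the I-splines); 0 outside
        the knot span."""
        yc = np.atleast_1d(self.clip(y))
        B = BSpline.design_matrix(yc, self._t, self._deg).toarray()
        return B / self._norms


@dataclass
class LinkFunction:
    """Monotone link H(y) = intercept + sum_k weights_k^2 I_k(y).

    ``weights`` are unconstrained; they enter squared, so H is non-decreasing
    by construction and invariant to their signs.  For identifiability with
    the latent class mixed model the intercept is fixed at 0 by default and
    the measurement-error SD at 1 (location and scale live in the class
    trajectory parameters).
    """

    knots: tuple
    weights: np.ndarray
    intercept: float = 0.0
    order: int = 3

    def __post_init__(self) -> None:
        self.basis = ISplineBasis(self.knots, self.order)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.basis.n_basis,):
            raise ValueError(
                f"link needs {self.basis.n_basis} weights, got {self.weights.shape}"
            )

    @classmethod
    def identity_like(cls, knots, scale: float = 1.0, order: int = 3) -> "LinkFunction":
        """Weights making H(y) = (y - knots[0]) / scale exactly.

        Constants lie in the M-spline span, so a linear H is representable;
        useful as an optimizer start and for likelihood cross-checks.
        """
        basis = ISplineBasis(knots, order)
        return cls(tuple(knots), np.sqrt(basis._norms / scale), 0.0, order)

    @property
    def coefficients(self) -> np.ndarray:
        """Non-negative I-spline coefficients w_k^2."""
        return self.weights**2

    def is_degenerate(self) -> bool:
        return not np.any(self.weights != 0.0)


def ispline_basis(y, link: LinkFunction) -> np.ndarray:
    """I-spline basis values of the link at intensities ``y`` (n x K)."""
    return link.basis.ibasis(y)


def transform(y, link: LinkFunction) -> np.ndarray:
    """H(y): observed intensity -> latent scale.  Values outside the knot
    span are clamped (with a warning above the upper knot)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(y > link.basis.hi):
        warnings.warn(
            f"{int(np.sum(y > link.basis.hi))} intensity value(s) above the upper "
            f"link knot {link.basis.hi}; clamped",
            stacklevel=2,
        )
    return link.intercept + link.basis.ibasis(y) @ link.coefficients


def derivative(y, link: LinkFunction) -> np.ndarray:
    """H'(y) = sum_k w_k^2 M_k(y), evaluated at the clamped intensity."""
    return link.basis.mbasis(y) @ link.coefficients


def inverse_transform(x, link: LinkFunction) -> np.ndarray:
    """H^{-1}(x) by monotone bisection; latent values outside
    [H(lo), H(hi)] map to the boundary intensities."""
    if link.is_degenerate():
        raise ValueError("flat link (all weights zero) has no inverse")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    lo = np.full(x.shape, link.basis.lo)
    hi = np.full(x.shape, link.basis.hi)
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        below = transform(mid, link) < x
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class TimeBasis:
    """Natural cubic spline basis specification for years-before-index.

    ``inner_knots`` default to the quartile placement 12/24/36 years;
    ``boundary_knots`` bracket the observed time range.
    """

    inner_knots: tuple = (12.0, 24.0, 36.0)
    boundary_knots: tuple = (0.0, 50.0)

    def __post_init__(self) -> None:
        ks = self.all_knots
        if len(ks) < 2 or np.any(np.diff(ks) <= 0):
            raise ValueError("time knots must be strictly increasing")

    @property
    def all_knots(self) -> np.ndarray:
        return np.r_[
            self.boundary_knots[0], np.asarray(self.inner_knots, float), self.boundary_knots[1]
        ]

    @property
    def n_basis(self) -> int:
        """Number of design columns (excluding the intercept)."""
        return len(self.inner_knots) + 1


def ncs_design(times, basis: TimeBasis) -> np.ndarray:
    """Natural cubic spline design matrix (no intercept column).

    Truncated-power construction: columns are [t, d_1 - d_{K-1}, ...,
    d_{K-2} - d_{K-1}] with d_k(t) = ((t - xi_k)_+^3 - (t - xi_K)_+^3) /
    (xi_K - xi_k).  Second derivatives vanish at and beyond the boundary
    knots, so extrapolation is linear.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times before the index date must be >= 0")
    xi = basis.all_knots
    K = len(xi)

    def d(k):
        return (
            np.maximum(t - xi[k], 0.0) ** 3 - np.maximum(t - xi[K - 1], 0.0) ** 3
        ) / (xi[K - 1] - xi[k])

    cols = [t]
    d_last = d(K - 2)
    for k in range(K - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols)
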