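"""M-spline / I-spline machinery for baseline hazards.

A baseline hazard is modelled as a non-negative combination of M-spline
basis functions, ``lambda_0(t) = sum_i eta_i M_i(t)`` with ``eta_i >= 0``.
M-splines are non-negative and each integrates to one over its support, so
positivity of the hazard is automatic and the cumulative hazard is the
matching I-spline combination.  The curvature penalty used by penalized
likelihood is the quadratic form ``eta' P eta`` with ``P`` the Gram matrix
of second derivatives, computed exactly by per-interval Gauss-Legendre
quadrature (the integrand is piecewise quadratic for cubic splines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "BaselineHazard", "SplineDomainError"]


class SplineDomainError(ValueError):
    """Evaluation requested outside the fitted time domain [0, t_max]."""


@dataclass(frozen=True)
class SplineBasis:
    """Cubic M-spline basis on [0, t_max].

    Parameters
    ----------
    interior_knots : strictly increasing knots in (0, t_max)
    t_max : right boundary of the domain
    order : spline order (4 = cubic, the default and only tested order)
    """

    interior_knots: tuple[float, ...]
    t_max: float
    order: int = 4

    def __post_init__(self) -> None:
        ik = tuple(float(k) for k in self.interior_knots)
        if any(b <= a for a, b in zip(ik, ik[1:])):
            raise ValueError("interior knots must be strictly increasing")
        if ik and not (0.0 < ik[0] and ik[-1] < self.t_max):
            raise ValueError("interior knots must lie strictly inside (0, t_max)")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        object.__setattr__(self, "interior_knots", ik)

    @property
    def knots(self) -> np.ndarray:
        """Full augmented knot vector (boundaries repeated `order` times)."""
        return np.concatenate(
            [
                np.zeros(self.order),
                np.asarray(self.interior_knots, dtype=float),
                np.full(self.order, float(self.t_max)),
            ]
        )

    @property
    def n_basis(self) -> int:
        return len(self.interior_knots) + self.order

    @classmethod
    def from_event_times(
        cls, event_times, n_basis: int = 7, t_max: float | None = None, order: int = 4
    ) -> "SplineBasis":
        """Place interior knots at equally spaced quantiles of event times."""
        times = np.asarray(event_times, dtype=float)
        if t_max is None:
            t_max = float(times.max())
        n_interior = n_basis - order
        if n_interior < 0:
            raise ValueError(f"n_basis must be >= order ({order})")
        if n_interior == 0:
            return cls((), t_max, order)
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        knots = np.quantile(times[(times > 0) & (times < t_max)], qs)
        # collapse of quantile knots (heavy ties) would break the basis
        knots = np.unique(np.clip(knots, 1e-8 * t_max, (1 - 1e-8) * t_max))
        if len(knots) < n_interior:
            knots = np.linspace(0, t_max, n_interior + 2)[1:-1]
        return cls(tuple(knots), t_max, order)

    # -- cached scipy spline objects -------------------------------------
    def _splines(self):
        cache = getattr(self, "_spl_cache", None)
        if cache is None:
            k = self.order - 1
            knots = self.knots
            m = self.n_basis
            # M_i = order * B_i / (t_{i+order} - t_i)
            norm = self.order / (knots[self.order :] - knots[:m])
            bs, ibs = [], []
            for i in range(m):
                c = np.zeros(m)
                c[i] = norm[i]
                b = BSpline(knots, c, k, extrapolate=False)
                bs.append(b)
                ibs.append(b.antiderivative())
            cache = (bs, ibs, norm)
            object.__setattr__(self, "_spl_cache", cache)
        return cache

    def _check_domain(self, t: np.ndarray) -> None:
        if np.any(t < 0) or np.any(t > self.t_max * (1 + 1e-12)):
            raise SplineDomainError(
                f"time outside spline domain [0, {self.t_max}]; refit with a "
                "larger t_max to evaluate there"
            )

    def basis_matrix(self, t) -> np.ndarray:
        """(len(t), m) matrix of M_i(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_domain(t)
        t = np.clip(t, 0.0, self.t_max)
        bs, _, _ = self._splines()
        out = np.column_stack([b(t) for b in bs])
        # scipy returns nan at exactly t = t_max for extrapolate=False
        return np.nan_to_num(out, nan=0.0) if np.isnan(out).any() else out

    def integral_matrix(self, t) -> np.ndarray:
        """(len(t), m) matrix of I_i(t) = int_0^t M_i."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        self._check_domain(t)
        t = np.clip(t, 0.0, self.t_max)
        _, ibs, _ = self._splines()
        cols = []
        for ib in ibs:
            v = ib(t)
            # right of the basis support the integral saturates at 1
            v = np.where(np.isnan(v), ib(self.t_max), v)
            cols.append(v)
        return np.column_stack(cols)

    def curvature_gram(self) -> np.ndarray:
        """Exact Gram matrix P with P_ij = int M_i'' M_j'' dt."""
        bs, _, _ = self._splines()
        d2 = [b.derivative(2) for b in bs]
        breaks = np.unique(self.knots)
        # second derivative of a cubic is piecewise linear: 2-point
        # Gauss-Legendre per interval integrates the product exactly
        gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
        gl_w = np.array([1.0, 1.0])
        m = self.n_basis
        P = np.zeros((m, m))
        for a, b_ in zip(breaks[:-1], breaks[1:]):
            h = 0.5 * (b_ - a)
            mid = 0.5 * (a + b_)
            pts = mid + h * gl_x
            vals = np.column_stack([np.nan_to_num(d(pts), nan=0.0) for d in d2])
            P += h * (vals.T * gl_w) @ vals
        return P

    def to_dict(self) -> dict:
        return {
            "interior_knots": list(self.interior_knots),
            "t_max": self.t_max,
            "order": self.order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        return cls(tuple(d["interior_knots"]), d["t_max"], d.get("order", 4))


@dataclass
class BaselineHazard:
    """Non-negative spline baseline hazard with coefficient vector eta."""

    basis: SplineBasis
    eta: np.ndarray

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.shape != (self.basis.n_basis,):
            raise ValueError(
                f"eta must have length {self.basis.n_basis}, got {self.eta.shape}"
            )
        if np.any(self.eta < 0):
            raise ValueError("spline coefficients must be non-negative")

    def hazard(self, t) -> np.ndarray:
        """lambda_0(t) = sum_i eta_i M_i(t)."""
        return self.basis.basis_matrix(t) @ self.eta

    def cumulative(self, t) -> np.ndarray:
        """Lambda_0(t) = int_0^t lambda_0; exactly 0 at t=0, non-decreasing."""
        return self.basis.integral_matrix(t) @ self.eta

    def curvature_penalty(self) -> float:
        """int (lambda_0''(t))^2 dt = eta' P eta."""
        P = self.basis.curvature_gram()
        return float(self.eta @ P @ self.eta)

    @property
    def t_max(self) -> float:
        return self.basis.t_max

    @classmethod
    def constant(cls, level: float, t_max: float, n_basis: int = 4) -> "BaselineHazard":
        """Hazard identically equal to `level` on [0, t_max].

        Uses the partition property: with eta_i = level * (t_{i+k} - t_i) / k
        the M-spline combination reproduces the constant exactly.
        """
        n_interior = max(n_basis - 4, 0)
        interior = tuple(np.linspace(0, t_max, n_interior + 2)[1:-1])
        basis = SplineBasis(interior, t_max)
        knots = basis.knots
        eta = level * (knots[basis.order :] - knots[: basis.n_basis]) / basis.order
        return cls(basis, eta)

    def to_dict(self) -> dict:
        return {"basis": self.basis.to_dict(), "eta": self.eta.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineHazard":
        return cls(SplineBasis.from_dict(d["basis"]), np.asarray(d["eta"]))
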