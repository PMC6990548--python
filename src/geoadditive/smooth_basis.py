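"""B-spline design matrices and random-walk penalties for Bayesian P-splines.

A smooth f(z) is expanded as sum_m alpha_m B_m(z) with M = n_inner + degree
cubic (by default) B-spline basis functions on equally spaced knots spanning
the covariate range.  The coefficients carry a first- or second-order
random-walk prior whose improper Gaussian density has precision tau2 * K,
K = D_d' D_d with D_d the d-th order difference operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineBasisSpec:
    """Equally spaced B-spline basis: degree, interior-interval count, knots."""

    degree: int
    n_inner: int
    knots: tuple[float, ...]  # n_inner + 1 equally spaced values incl. both ends

    @property
    def n_basis(self) -> int:
        """Number of basis functions M = n_inner + degree."""
        return self.n_inner + self.degree

    @property
    def span(self) -> tuple[float, float]:
        return self.knots[0], self.knots[-1]

    def to_dict(self) -> dict:
        return {"degree": self.degree, "n_inner": self.n_inner, "knots": list(self.knots)}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasisSpec":
        return cls(degree=int(d["degree"]), n_inner=int(d["n_inner"]), knots=tuple(d["knots"]))


@dataclass(frozen=True)
class PenaltyMatrix:
    """Random-walk penalty K = D_d' D_d of order d; rank M - d."""

    order: int
    K: np.ndarray = field(repr=False)

    @property
    def rank(self) -> int:
        return self.K.shape[0] - self.order


def make_basis_spec(z_values, degree: int = 3, n_inner: int = 17) -> SplineBasisSpec:
    """Basis spec with ``n_inner`` equal intervals over the range of ``z_values``.

    Raises
    ------
    ValueError
        If the covariate is constant, or degree/n_inner are out of range.
    """
    z = np.asarray(z_values, dtype=float)
    if degree < 1:
        raise ValueError(f"spline degree must be >= 1, got {degree}")
    if n_inner < 1:
        raise ValueError(f"n_inner must be >= 1, got {n_inner}")
    zmin, zmax = float(np.min(z)), float(np.max(z))
    if not zmax > zmin:
        raise ValueError("covariate is constant; cannot build a spline basis")
    knots = np.linspace(zmin, zmax, n_inner + 1)
    return SplineBasisSpec(degree=degree, n_inner=n_inner, knots=tuple(knots))


def bspline_design(z_values, spec: SplineBasisSpec) -> np.ndarray:
    """Dense n x M B-spline design matrix; rows sum to one (partition of unity).

    Boundary knots are clamped (repeated ``degree`` times) so the basis is
    well defined on the closed span; values outside the span are rejected
    rather than extrapolated.
    """
    z = np.atleast_1d(np.asarray(z_values, dtype=float))
    lo, hi = spec.span
    if np.any(z < lo) or np.any(z > hi):
        bad = z[(z < lo) | (z > hi)][0]
        raise ValueError(f"value {bad} outside the knot span [{lo}, {hi}]; no extrapolation")
    t = np.r_[np.full(spec.degree, lo), spec.knots, np.full(spec.degree, hi)]
    design = BSpline.design_matrix(z, t, spec.degree, extrapolate=False)
    B = np.asarray(design.todense())
    assert B.shape == (z.size, spec.n_basis)
    return B


def rw_penalty(n_basis: int, order: int = 2) -> PenaltyMatrix:
    """Random-walk penalty of the given order for ``n_basis`` coefficients."""
    if order not in (1, 2):
        raise ValueError(f"random-walk order must be 1 or 2, got {order}")
    if n_basis <= order:
        raise ValueError(f"need n_basis > order, got n_basis={n_basis}, order={order}")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return PenaltyMatrix(order=order, K=D.T @ D)
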