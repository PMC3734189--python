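"""Minimum-volume enclosing ellipsoids and quadratic (Mahalanobis) distances.

A cell's anisotropy is summarized by an ellipsoid ``(c, M)``: the locus
``(x - c)^T M (x - c) = 1`` with ``M`` symmetric positive definite.  The same
pair doubles as the site parameters of one region of a quadratic Voronoi
diagram, where the distance from ``x`` to the site is the squared Mahalanobis
distance ``(x - c)^T M (x - c)``.

The fitter solves the Loewner–John problem — the minimum-volume ellipsoid
enclosing a finite point set — through its dual: maximize ``log det`` of the
weighted scatter of the lifted points over barycentric weights ``u``.  The
iteration is Khachiyan's coordinate ascent with Wolfe–Atwood "away" steps,
which is deterministic and fast for the few hundred to few thousand boundary
points a single cell contributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    ConvergenceError,
    DegenerateGeometryError,
    ShapeError,
    ValidationError,
)

__all__ = [
    "Ellipsoid",
    "MveeResult",
    "fit_mvee",
    "mahalanobis_sq",
    "ellipsoid_volume",
]

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class Ellipsoid:
    """Center-form ellipsoid ``(x - center)^T shape (x - center) <= 1``.

    ``center`` is in µm, ``shape`` in µm^-2.  ``shape`` must be symmetric
    positive definite; eigenvalue ``lam`` corresponds to a semi-axis of
    length ``1/sqrt(lam)``.
    """

    center: np.ndarray
    shape: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float).ravel()
        M = np.asarray(self.shape, dtype=float)
        if M.shape != (c.size, c.size):
            raise ShapeError(
                f"shape matrix is {M.shape}, expected ({c.size}, {c.size})"
            )
        scale = float(np.abs(M).max()) or 1.0
        if not np.allclose(M, M.T, atol=_SYM_TOL * scale, rtol=0.0):
            raise ValidationError("shape matrix is not symmetric")
        M = 0.5 * (M + M.T)
        if np.linalg.eigvalsh(M).min() <= 0.0:
            raise ValidationError("shape matrix is not positive definite")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "shape", M)

    @property
    def dim(self) -> int:
        return self.center.size

    @property
    def semi_axes(self) -> np.ndarray:
        """Semi-axis lengths (µm), ascending."""
        lams = np.linalg.eigvalsh(self.shape)
        return 1.0 / np.sqrt(lams[::-1])

    def volume(self) -> float:
        return ellipsoid_volume(self)


@dataclass(frozen=True)
class MveeResult:
    """Solution of a minimum-volume enclosing ellipsoid fit.

    ``support_weights`` are the dual barycentric variables; they are
    nonnegative, sum to one, and are positive only on contact points.
    """

    ellipsoid: Ellipsoid
    iterations: int
    achieved_tol: float
    support_weights: np.ndarray


def _affine_rank(points: np.ndarray, rel_tol: float = 1e-9):
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = svals[0] if svals.size and svals[0] > 0 else 1.0
    rank = int(np.sum(svals > rel_tol * scale))
    return rank, svals, scale


def fit_mvee(points, tol: float = 1e-4, max_iter: int = 10_000) -> MveeResult:
    """Fit the minimum-volume ellipsoid enclosing ``points``.

    Parameters
    ----------
    points : (n, d) array_like
        At least ``d + 1`` points that affinely span d dimensions.
    tol : float
        Containment tolerance: on return every point satisfies
        ``(p - c)^T M (p - c) <= 1 + tol``.
    max_iter : int
        Iteration cap of the dual ascent.

    Raises
    ------
    DegenerateGeometryError
        If the points are rank deficient (e.g. coplanar in 3D): no
        finite-volume enclosing ellipsoid minimizer exists.
    ConvergenceError
        If the tolerance is not reached within ``max_iter`` iterations.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2:
        raise ShapeError("points must be a 2-D array of shape (n, d)")
    n, d = P.shape
    if tol <= 0:
        raise ValidationError("tol must be positive")
    if n < d + 1:
        raise DegenerateGeometryError(
            f"need at least {d + 1} points in {d}-D, got {n}",
            deficient_dims=d,
        )
    rank, _, _ = _affine_rank(P)
    if rank < d:
        raise DegenerateGeometryError(
            f"points affinely span only {rank} of {d} dimensions",
            deficient_dims=d - rank,
        )

    # Lifted points q_i = (p_i, 1); dual objective is log det sum u_i q_i q_i^T.
    Q = np.hstack([P, np.ones((n, 1))])  # (n, d+1)
    u = np.full(n, 1.0 / n)
    # Dual gap eps = max_i kappa_i/(d+1) - 1 bounds the containment excess by
    # eps*(d+1)/d, so iterate to a proportionally tighter dual tolerance.
    dual_tol = tol * d / (d + 1)

    it = 0
    eps = np.inf
    for it in range(1, max_iter + 1):
        X = Q.T @ (u[:, None] * Q)
        Xinv = np.linalg.inv(X)
        kappa = np.einsum("ij,jk,ik->i", Q, Xinv, Q)
        j_up = int(np.argmax(kappa))
        eps = kappa[j_up] / (d + 1) - 1.0
        if eps <= dual_tol:
            break
        support = u > 0
        kappa_support = np.where(support, kappa, np.inf)
        j_dn = int(np.argmin(kappa_support))
        e_dn = 1.0 - kappa[j_dn] / (d + 1)
        if eps >= e_dn:
            k = kappa[j_up]
            step = (k - d - 1.0) / ((d + 1.0) * (k - 1.0))
            j = j_up
        else:
            # Away step: reduce the weight of an interior support point.
            # The closed-form optimum only applies for kappa > 1; deeper
            # points are dropped outright.
            k = kappa[j_dn]
            full_drop = -u[j_dn] / (1.0 - u[j_dn])
            if k <= 1.0:
                step = full_drop
            else:
                step = max((k - d - 1.0) / ((d + 1.0) * (k - 1.0)), full_drop)
            j = j_dn
        u *= 1.0 - step
        u[j] += step
        np.clip(u, 0.0, None, out=u)
        u /= u.sum()
    else:
        raise ConvergenceError(
            f"MVEE did not converge in {max_iter} iterations "
            f"(dual gap {eps:.3g}, requested {dual_tol:.3g})",
            achieved_tol=float(eps * (d + 1) / d),
        )

    c = Q[:, :d].T @ u
    cov = (P * u[:, None]).T @ P - np.outer(c, c)
    M = np.linalg.inv(cov) / d
    M = 0.5 * (M + M.T)
    ell = Ellipsoid(center=c, shape=M)
    diffs = P - c
    maha = np.einsum("ij,jk,ik->i", diffs, M, diffs)
    achieved = max(0.0, float(maha.max()) - 1.0)
    return MveeResult(
        ellipsoid=ell,
        iterations=it,
        achieved_tol=achieved,
        support_weights=u,
    )


def mahalanobis_sq(e: Ellipsoid, x) -> float | np.ndarray:
    """Squared Mahalanobis distance ``(x - c)^T M (x - c)``.

    Accepts a single d-vector (returns a scalar) or an ``(n, d)`` array
    (returns an ``(n,)`` array).  The value is 0 exactly at the center and
    1 on the ellipsoid surface.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != e.dim:
        raise ShapeError(f"point dimension {X.shape[1]} != ellipsoid dim {e.dim}")
    diffs = X - e.center
    vals = np.einsum("ij,jk,ik->i", diffs, e.shape, diffs)
    return float(vals[0]) if single else vals


def ellipsoid_volume(e: Ellipsoid) -> float:
    """Volume (µm^d): unit-ball volume of dimension d over ``sqrt(det M)``."""
    d = e.dim
    det = np.linalg.det(e.shape)
    if det <= 0:
        raise ValidationError("shape matrix must be positive definite")
    unit_ball = math.pi ** (d / 2.0) / math.gamma(d / 2.0 + 1.0)
    return unit_ball / math.sqrt(det)
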