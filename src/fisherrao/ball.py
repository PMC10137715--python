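"""Smallest enclosing Riemannian balls for SPD matrices and normals.

The SPD cone under the trace metric is a Hadamard manifold, so the farthest
point iteration — step from the current center a fraction 1/(t+1) along the
geodesic toward the farthest input — converges to the minimax circumcenter.
A set of d-variate normals is handled by embedding each as a (d+1) x (d+1)
SPD matrix (Calvo-Oller), running the SPD solver there, and projecting the
resulting center back onto the embedded normal submanifold.  When all
normals share a covariance the Fisher-Rao and Calvo-Oller distances are
strictly increasing functions of the Mahalanobis distance of the means, so
the exact circumcenter reduces to a Euclidean smallest enclosing ball of the
whitened means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .calvo_oller import embed, project_to_embedding, rho_co, unembed
from .gaussian import Gaussian, validate_spd
from .spd import rho_p, rho_spd, spd_geodesic_factory

__all__ = [
    "BallResult",
    "rieseb_spd",
    "fr_circumball",
    "same_cov_circumcenter",
    "euclidean_miniball",
]


@dataclass(frozen=True)
class BallResult:
    """Approximate smallest enclosing Fisher-Rao ball of a set of normals."""

    center: Gaussian
    center_spd: np.ndarray
    radius_co: float
    projection_gap: float
    iterations: int


def rieseb_spd(
    Ps: Sequence[np.ndarray], T: int, *, early_stop: float | None = 1e-10
) -> np.ndarray:
    """Farthest-point iteration for the smallest enclosing ball in the SPD
    cone: ``C_1 = P_1`` and ``C_{t+1} = gamma(C_t, P_far; 1/(t+1))``.

    Ties for the farthest input break toward the lowest index; iteration
    stops early once the center moves less than ``early_stop`` in rho_P.
    """
    if len(Ps) == 0:
        raise ValueError("input set must be nonempty")
    Ps = [validate_spd(P, f"P[{i}]") for i, P in enumerate(Ps)]
    n = Ps[0].shape[0]
    if any(P.shape != (n, n) for P in Ps):
        raise ValueError("all matrices must share a common size")
    if T < 1:
        raise ValueError("T must be a positive integer")
    C = Ps[0]
    for t in range(1, T):
        dists = [rho_spd(C, P) for P in Ps]
        far = int(np.argmax(dists))  # argmax returns the first maximizer
        Cnext = spd_geodesic_factory(C, Ps[far])(1.0 / (t + 1))
        if early_stop is not None and rho_p(C, Cnext) < early_stop:
            return Cnext
        C = Cnext
    return C


def fr_circumball(Gs: Sequence[Gaussian], T: int) -> BallResult:
    """Approximate smallest enclosing Fisher-Rao ball of a set of normals.

    Embed, solve the SPD enclosing ball, project the center back onto the
    embedded submanifold, and recompute the Calvo-Oller radius against the
    inputs.  ``projection_gap`` (rho_P between the pre- and post-projection
    centers) indicates the quality of the approximation.
    """
    if len(Gs) == 0:
        raise ValueError("input set must be nonempty")
    d = Gs[0].d
    if any(g.d != d for g in Gs):
        raise ValueError("all Gaussians must share a common dimension")
    embedded = [embed(g).matrix for g in Gs]
    C = rieseb_spd(embedded, T)
    proj, gap = project_to_embedding(C)
    center, _ = unembed(proj)
    radius = max(rho_co(center, g) for g in Gs)
    return BallResult(center, proj.matrix, radius, gap, T)


def _circumsphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Center/radius of the smallest sphere through <= d+1 affinely
    independent points: the circumcenter within their affine hull."""
    p0 = points[0]
    A = points[1:] - p0
    # c = p0 + A^T alpha with 2 (A A^T) alpha = diag(A A^T)
    G = A @ A.T
    alpha = np.linalg.solve(2.0 * G, np.diag(G))
    c = p0 + A.T @ alpha
    return c, float(np.linalg.norm(points[0] - c))


def euclidean_miniball(
    points: np.ndarray, tol: float = 1e-12
) -> tuple[np.ndarray, float]:
    """Exact smallest enclosing Euclidean ball (Welzl's move-to-front
    algorithm, deterministic insertion order)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = pts.shape
    if n > 1000:
        # farthest-point iteration: cheap and accurate enough at this size
        c = pts[0].copy()
        for t in range(1, 100_000):
            dists = np.linalg.norm(pts - c, axis=1)
            far = int(np.argmax(dists))
            step = (pts[far] - c) / (t + 1)
            c += step
            if np.linalg.norm(step) < tol:
                break
        return c, float(np.max(np.linalg.norm(pts - c, axis=1)))

    def ball(boundary: list[int]) -> tuple[np.ndarray, float]:
        if not boundary:
            return np.zeros(d), -1.0
        if len(boundary) == 1:
            return pts[boundary[0]].copy(), 0.0
        return _circumsphere(pts[boundary])

    def welzl(idx: list[int], boundary: list[int]) -> tuple[np.ndarray, float]:
        if not idx or len(boundary) == d + 1:
            return ball(boundary)
        rest = idx[1:]
        c, r = welzl(rest, boundary)
        p = pts[idx[0]]
        if np.linalg.norm(p - c) <= r + tol:
            return c, r
        return welzl(rest, boundary + [idx[0]])

    import sys

    limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(limit, 4 * n + 100))
    try:
        return welzl(list(range(n)), [])
    finally:
        sys.setrecursionlimit(limit)


def same_cov_circumcenter(
    mus: Sequence[np.ndarray], sigma: np.ndarray
) -> Gaussian:
    """Exact circumcenter for normals sharing covariance ``Sigma``.

    Whiten the means by the Cholesky factor of Sigma, take the Euclidean
    smallest enclosing ball, and map its center back; since both the
    Fisher-Rao and Calvo-Oller distances are strictly increasing in the
    Mahalanobis distance, this minimax center is exact for both.
    """
    sigma = validate_spd(sigma, "Sigma")
    M = np.atleast_2d(np.asarray(mus, dtype=float))
    if M.shape[1] != sigma.shape[0]:
        raise ValueError("mean / Sigma dimension mismatch")
    L = cholesky(sigma, lower=True)
    Z = solve_triangular(L, M.T, lower=True).T
    c, _ = euclidean_miniball(Z)
    return Gaussian(L @ c, sigma)
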