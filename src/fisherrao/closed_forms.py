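"""Exact Fisher-Rao distances for tractable normal subfamilies, and bounds.

Closed forms exist for three subfamilies:

* univariate normals — hyperbolic (Poincare upper half-plane) geometry,
  ``rho_N = sqrt(2) log((1 + Delta)/(1 - Delta))`` with the cross-ratio
  ``Delta(mu1, s1; mu2, s2)``;
* common mean — the fixed-mean submanifold is totally geodesic, so the
  distance is the SPD cone distance ``rho_p`` of the covariances;
* common covariance — the distance is a strictly increasing scalar function
  ``h_fr`` of the Mahalanobis distance between the means (a maximal
  invariant of the translation action).

In addition this module provides the closed-form upper bounds on the general
Fisher-Rao distance: the triangle-inequality bound through a common-mean
corner, the Strapasson-Porto-Costa (SPC) bound, and the square root of the
Jeffreys divergence.
"""

from __future__ import annotations

import numpy as np

from .gaussian import Gaussian, jeffreys, mahalanobis, validate_spd
from .spd import rho_p, spd_function

__all__ = [
    "delta_ratio",
    "rho_univariate",
    "rho_same_mean",
    "h_fr",
    "h_co",
    "rho_same_cov",
    "rho_co_same_cov",
    "project_fixed_mean",
    "project_fixed_cov",
    "fixed_mean_projection_distance",
    "upper_bound_triangle",
    "spc_upper_bound",
    "jeffreys_upper_bound",
]

_SQRT2 = np.sqrt(2.0)


def _arccosh1p(x: float) -> float:
    """arccosh(1 + x) for x >= 0, accurate for small x (avoids the
    cancellation in forming 1 + x)."""
    return float(np.log1p(x + np.sqrt(x * (x + 2.0))))


def delta_ratio(a: float, b: float, c: float, d: float) -> float:
    """Cross-ratio term of the univariate hyperbolic distance:

        Delta(a, b; c, d) = sqrt(((c-a)^2 + 2(d-b)^2) / ((c-a)^2 + 2(d+b)^2))

    for scale parameters b, d > 0.  Lies in [0, 1); zero iff (a,b) = (c,d).
    """
    if b <= 0 or d <= 0:
        raise ValueError("scale parameters must be positive")
    num = (c - a) ** 2 + 2.0 * (d - b) ** 2
    den = (c - a) ** 2 + 2.0 * (d + b) ** 2
    return float(np.sqrt(num / den))


def rho_univariate(g1: Gaussian, g2: Gaussian) -> float:
    """Fisher-Rao distance between univariate normals,
    ``sqrt(2) log((1+Delta)/(1-Delta)) = 2 sqrt(2) arctanh(Delta)``."""
    if g1.d != 1 or g2.d != 1:
        raise ValueError("rho_univariate requires d=1 inputs")
    delta = delta_ratio(
        float(g1.mean[0]),
        float(np.sqrt(g1.cov[0, 0])),
        float(g2.mean[0]),
        float(np.sqrt(g2.cov[0, 0])),
    )
    return float(2.0 * _SQRT2 * np.arctanh(delta))


def rho_same_mean(S1: np.ndarray, S2: np.ndarray) -> float:
    """Fisher-Rao distance between normals sharing a mean:
    ``sqrt(1/2 sum_i log^2 lambda_i(S1^-1 S2))`` — the fixed-mean submanifold
    is totally geodesic, so this equals the full Fisher-Rao distance."""
    return rho_p(S1, S2)


def h_fr(u: float) -> float:
    """Fisher-Rao distance as a function of the Mahalanobis distance u for
    normals sharing a covariance: ``sqrt(2) arccosh(1 + u^2 / 4)``."""
    if u < 0:
        raise ValueError("u must be nonnegative")
    return _SQRT2 * _arccosh1p(0.25 * u * u)


def h_co(u: float) -> float:
    """Calvo-Oller distance as a function of the Mahalanobis distance for
    shared covariance: ``arccosh(1 + u^2 / 2)``; satisfies
    ``h_co(u) <= h_fr(u) <= u``."""
    if u < 0:
        raise ValueError("u must be nonnegative")
    return _arccosh1p(0.5 * u * u)


def rho_same_cov(mu1: np.ndarray, mu2: np.ndarray, sigma: np.ndarray) -> float:
    """Fisher-Rao distance between ``N(mu1, Sigma)`` and ``N(mu2, Sigma)``:
    ``h_fr`` of their Mahalanobis distance (translation-invariant)."""
    return h_fr(mahalanobis(mu1, mu2, sigma))


def rho_co_same_cov(mu1: np.ndarray, mu2: np.ndarray, sigma: np.ndarray) -> float:
    """Calvo-Oller distance for a shared covariance: ``h_co`` of the
    Mahalanobis distance; agrees with the general embedded-matrix route."""
    return h_co(mahalanobis(mu1, mu2, sigma))


def project_fixed_mean(g1: Gaussian, mu2: np.ndarray) -> Gaussian:
    """Fisher-Rao orthogonal projection of ``g1`` onto the submanifold of
    normals with mean ``mu2``:

        N* = N(mu2, Sigma1 + 1/2 (mu2 - mu1)(mu2 - mu1)^T).
    """
    mu2 = np.atleast_1d(np.asarray(mu2, dtype=float))
    if mu2.shape[0] != g1.d:
        raise ValueError("dimension mismatch")
    dm = mu2 - g1.mean
    return Gaussian(mu2, g1.cov + 0.5 * np.outer(dm, dm))


def fixed_mean_projection_distance(g1: Gaussian, mu2: np.ndarray) -> float:
    """Experimental closed form for the distance from ``g1`` to its
    fixed-mean projection: ``(1/sqrt 2) arccosh(d + dm^T Sigma1^-1 dm)``.

    Exact for d=1 (it matches the univariate closed form); for d >= 2 the
    expression does not vanish at mu2 = mu1 and should be treated as a
    heuristic only — validate against discretized curve lengths.
    """
    u = mahalanobis(g1.mean, mu2, g1.cov)
    return float(np.arccosh(g1.d + u * u) / _SQRT2)


def project_fixed_cov(g1: Gaussian, sigma2: np.ndarray) -> tuple[Gaussian, float]:
    """Fisher-Rao "vertical" projection of ``g1`` onto the submanifold of
    normals with covariance ``Sigma2``: the point ``N(mu1, Sigma2)`` at
    distance ``rho_same_mean(Sigma1, Sigma2)``."""
    sigma2 = validate_spd(sigma2, "Sigma2")
    if sigma2.shape[0] != g1.d:
        raise ValueError("dimension mismatch")
    return Gaussian(g1.mean, sigma2), rho_same_mean(g1.cov, sigma2)


def upper_bound_triangle(g1: Gaussian, g2: Gaussian) -> float:
    """Triangle-inequality upper bound through the corner ``(mu1, Sigma2)``:

        rho_N <= rho_p(Sigma1, Sigma2) + min(Delta_Sigma1, Delta_Sigma2),

    where the Mahalanobis distance bounds the fixed-covariance leg (that
    submanifold is not totally geodesic)."""
    if g1.d != g2.d:
        raise ValueError("dimension mismatch")
    leg = rho_same_mean(g1.cov, g2.cov)
    d1 = mahalanobis(g1.mean, g2.mean, g1.cov)
    d2 = mahalanobis(g1.mean, g2.mean, g2.cov)
    return leg + min(d1, d2)


def spc_upper_bound(g1: Gaussian, g2: Gaussian) -> float:
    """Strapasson-Porto-Costa upper bound on the Fisher-Rao distance.

    Whiten by Sigma1, diagonalize ``Sigmatilde = Sigma1^(-1/2) Sigma2
    Sigma1^(-1/2) = Omega D Omega^T``, rotate the whitened mean gap
    ``m = Omega^T Sigma1^(-1/2)(mu2 - mu1)``, and accumulate per-coordinate
    hyperbolic terms:

        U = sqrt(2 sum_i log^2((A_i + B_i)/(A_i - B_i))),
        A_i = sqrt((1 + D_ii)^2 + m_i^2),  B_i = sqrt((1 - D_ii)^2 + m_i^2).
    """
    if g1.d != g2.d:
        raise ValueError("dimension mismatch")
    isqrt = spd_function(g1.cov, "inv-sqrt")
    St = isqrt @ g2.cov @ isqrt
    D, Om = np.linalg.eigh((St + St.T) / 2.0)
    m = Om.T @ (isqrt @ (g2.mean - g1.mean))
    A = np.sqrt((1.0 + D) ** 2 + m**2)
    B = np.sqrt((1.0 - D) ** 2 + m**2)
    # A > B strictly since D > 0, so the ratio is finite and >= 1
    logs = np.log((A + B) / (A - B))
    return float(np.sqrt(2.0 * np.sum(logs**2)))


def jeffreys_upper_bound(g1: Gaussian, g2: Gaussian) -> float:
    """Square root of the Jeffreys divergence: an upper bound on the
    Fisher-Rao distance (Cauchy-Schwarz on the exponential geodesic energy),
    tight for nearby normals."""
    return float(np.sqrt(jeffreys(g1, g2)))
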