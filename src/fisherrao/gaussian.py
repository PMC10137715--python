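"""Multivariate normal distributions and their exponential-family structure.

A d-variate normal ``N(mu, Sigma)`` is the central object of this package.
Besides the source parameterization ``(mu, Sigma)`` we expose the natural
parameterization ``theta = (Sigma^-1 mu, 1/2 Sigma^-1)`` (with sufficient
statistic ``(x, -x x^T)``) and the expectation (moment) parameterization
``eta = (mu, -Sigma - mu mu^T)``, together with the log-partition function,
its convex conjugate, Kullback-Leibler / Jeffreys divergences, the
Mahalanobis distance, the affine group action and the Fisher line element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

__all__ = [
    "Gaussian",
    "NaturalParam",
    "ExpectationParam",
    "AffineMap",
    "validate_spd",
    "to_natural",
    "from_natural",
    "to_expectation",
    "from_expectation",
    "log_partition",
    "dual_potential",
    "kl_divergence",
    "jeffreys",
    "mahalanobis",
    "affine_act",
    "fisher_line_element",
    "bregman_fy",
    "fenchel_young",
]

#: relative eigenvalue floor below which a symmetric matrix is rejected
SPD_RTOL = 1e-12


def validate_spd(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Symmetrize ``M`` as ``(M + M^T)/2`` and verify positive-definiteness.

    Raises ``ValueError`` when ``M`` is not square, not finite, or its
    smallest eigenvalue is below ``SPD_RTOL`` times its spectral norm.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {M.shape}")
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains non-finite entries")
    M = (M + M.T) / 2.0
    w = np.linalg.eigvalsh(M)
    scale = max(w[-1], 0.0)
    if scale <= 0.0 or w[0] <= SPD_RTOL * scale:
        raise ValueError(
            f"{name} is not positive-definite "
            f"(min eigenvalue {w[0]:.3e}, max {w[-1]:.3e})"
        )
    return M


@dataclass(frozen=True)
class Gaussian:
    """A multivariate normal ``N(mean, cov)``.

    The covariance is symmetrized on construction and must be strictly
    positive-definite; dimensions of mean and covariance must agree.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        if mean.ndim != 1:
            raise ValueError("mean must be a vector")
        if not np.all(np.isfinite(mean)):
            raise ValueError("mean contains non-finite entries")
        cov = validate_spd(np.atleast_2d(self.cov), "cov")
        if cov.shape[0] != mean.shape[0]:
            raise ValueError(
                f"dimension mismatch: mean has d={mean.shape[0]}, "
                f"cov is {cov.shape[0]}x{cov.shape[1]}"
            )
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)

    @property
    def d(self) -> int:
        return self.mean.shape[0]

    def allclose(self, other: "Gaussian", atol: float = 1e-10) -> bool:
        return (
            self.d == other.d
            and np.allclose(self.mean, other.mean, atol=atol)
            and np.allclose(self.cov, other.cov, atol=atol)
        )


@dataclass(frozen=True)
class NaturalParam:
    """Natural parameters ``(theta_v, theta_M) = (Sigma^-1 mu, 1/2 Sigma^-1)``."""

    theta_v: np.ndarray
    theta_M: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.theta_v, dtype=float))
        M = validate_spd(np.atleast_2d(self.theta_M), "theta_M")
        if M.shape[0] != v.shape[0]:
            raise ValueError("theta_v / theta_M dimension mismatch")
        object.__setattr__(self, "theta_v", v)
        object.__setattr__(self, "theta_M", M)

    @property
    def d(self) -> int:
        return self.theta_v.shape[0]


@dataclass(frozen=True)
class ExpectationParam:
    """Moment parameters ``(eta_v, eta_H) = (mu, -Sigma - mu mu^T)``."""

    eta_v: np.ndarray
    eta_H: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.eta_v, dtype=float))
        H = np.atleast_2d(np.asarray(self.eta_H, dtype=float))
        H = (H + H.T) / 2.0
        # recoverable covariance -eta_H - eta_v eta_v^T must be SPD
        validate_spd(-H - np.outer(v, v), "recovered covariance")
        object.__setattr__(self, "eta_v", v)
        object.__setattr__(self, "eta_H", H)

    @property
    def d(self) -> int:
        return self.eta_v.shape[0]


@dataclass(frozen=True)
class AffineMap:
    """An element ``(A, a)`` of the affine group acting as ``x -> A x + a``."""

    A: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if A.shape[0] != A.shape[1] or A.shape[0] != a.shape[0]:
            raise ValueError("A must be square and match a in dimension")
        if abs(np.linalg.det(A)) <= np.finfo(float).tiny:
            raise ValueError("A must be invertible")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "a", a)

    def compose(self, other: "AffineMap") -> "AffineMap":
        """Group law ``(a1,A1).(a2,A2) = (a1 + A1 a2, A1 A2)``."""
        return AffineMap(self.A @ other.A, self.a + self.A @ other.a)

    def inverse(self) -> "AffineMap":
        Ainv = np.linalg.inv(self.A)
        return AffineMap(Ainv, -Ainv @ self.a)


# ---------------------------------------------------------------------------
# reparameterizations

def to_natural(g: Gaussian) -> NaturalParam:
    prec = np.linalg.inv(g.cov)
    prec = (prec + prec.T) / 2.0
    return NaturalParam(prec @ g.mean, prec / 2.0)


def from_natural(theta: NaturalParam) -> Gaussian:
    cov = np.linalg.inv(2.0 * theta.theta_M)
    cov = (cov + cov.T) / 2.0
    return Gaussian(cov @ theta.theta_v, cov)


def to_expectation(g: Gaussian) -> ExpectationParam:
    return ExpectationParam(g.mean, -g.cov - np.outer(g.mean, g.mean))


def from_expectation(eta: ExpectationParam) -> Gaussian:
    return Gaussian(eta.eta_v, -eta.eta_H - np.outer(eta.eta_v, eta.eta_v))


def to_cholesky(g: Gaussian) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(mu, L)`` with ``Sigma = L L^T`` and L lower-triangular."""
    return g.mean, cholesky(g.cov, lower=True)


def from_cholesky(mean: np.ndarray, L: np.ndarray) -> Gaussian:
    L = np.atleast_2d(np.asarray(L, dtype=float))
    return Gaussian(mean, L @ L.T)


# ---------------------------------------------------------------------------
# potentials and divergences

def log_partition(theta: NaturalParam) -> float:
    """Log-normalizer F(theta) of the normal exponential family.

    With sufficient statistic ``t(x) = (x, -x x^T)`` the density is
    ``exp(theta_v . x - x^T theta_M x - F(theta))`` and

        F(theta) = d/2 log(pi) - 1/2 log|theta_M| + 1/4 theta_v^T theta_M^-1 theta_v

    so that ``grad F(theta) = eta`` (the moment parameters) and the Bregman
    divergence of F is the reverse Kullback-Leibler divergence.
    """
    d = theta.d
    c = cho_factor(theta.theta_M)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    quad = theta.theta_v @ cho_solve(c, theta.theta_v)
    return 0.5 * d * np.log(np.pi) - 0.5 * logdet + 0.25 * quad


def dual_potential(eta: ExpectationParam) -> float:
    """Convex conjugate F*(eta) = Shannon negentropy of the normal.

    ``F*(eta) = -1/2 log((2 pi e)^d |Sigma|)`` where
    ``Sigma = -eta_H - eta_v eta_v^T``.
    """
    d = eta.d
    cov = -eta.eta_H - np.outer(eta.eta_v, eta.eta_v)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("eta does not encode a positive-definite covariance")
    return -0.5 * (d * np.log(2.0 * np.pi * np.e) + logdet)


def _inner(theta: NaturalParam, eta: ExpectationParam) -> float:
    """Duality pairing <theta, eta> for statistic (x, -x x^T): note eta_H
    already carries the minus sign, so the pairing is a plain sum."""
    return float(theta.theta_v @ eta.eta_v + np.sum(theta.theta_M * eta.eta_H))


def kl_divergence(g1: Gaussian, g2: Gaussian) -> float:
    """Kullback-Leibler divergence KL(N1 : N2), in nats.

    ``KL = 1/2 [tr(Sigma2^-1 Sigma1) + dmu^T Sigma2^-1 dmu - d + log(|Sigma2|/|Sigma1|)]``
    """
    if g1.d != g2.d:
        raise ValueError(f"dimension mismatch: {g1.d} vs {g2.d}")
    d = g1.d
    dm = g2.mean - g1.mean
    c2 = cho_factor(g2.cov)
    tr = np.trace(cho_solve(c2, g1.cov))
    quad = dm @ cho_solve(c2, dm)
    _, ld1 = np.linalg.slogdet(g1.cov)
    ld2 = 2.0 * np.sum(np.log(np.diag(c2[0])))
    return 0.5 * (tr + quad - d + ld2 - ld1)


def jeffreys(g1: Gaussian, g2: Gaussian) -> float:
    """Jeffreys divergence ``DJ = KL(N1:N2) + KL(N2:N1)`` (symmetric).

    The log-determinant terms cancel:
    ``DJ = tr((Sigma2^-1 Sigma1 + Sigma1^-1 Sigma2)/2 - I)
    + dmu^T (Sigma1^-1 + Sigma2^-1)/2 dmu``.
    """
    if g1.d != g2.d:
        raise ValueError(f"dimension mismatch: {g1.d} vs {g2.d}")
    d = g1.d
    dm = g2.mean - g1.mean
    c1 = cho_factor(g1.cov)
    c2 = cho_factor(g2.cov)
    tr = 0.5 * (np.trace(cho_solve(c2, g1.cov)) + np.trace(cho_solve(c1, g2.cov)))
    quad = 0.5 * (dm @ cho_solve(c1, dm) + dm @ cho_solve(c2, dm))
    return tr - d + quad


def mahalanobis(mu1: np.ndarray, mu2: np.ndarray, sigma: np.ndarray) -> float:
    """Mahalanobis distance ``sqrt((mu2-mu1)^T Sigma^-1 (mu2-mu1))``."""
    sigma = validate_spd(sigma, "Sigma")
    dm = np.atleast_1d(np.asarray(mu2, dtype=float)) - np.atleast_1d(
        np.asarray(mu1, dtype=float)
    )
    if dm.shape[0] != sigma.shape[0]:
        raise ValueError("mean / Sigma dimension mismatch")
    c = cho_factor(sigma)
    return float(np.sqrt(dm @ cho_solve(c, dm)))


def affine_act(m: AffineMap, g: Gaussian) -> Gaussian:
    """Affine group action ``(A, a) . N(mu, Sigma) = N(A mu + a, A Sigma A^T)``."""
    if m.A.shape[0] != g.d:
        raise ValueError("affine map / Gaussian dimension mismatch")
    return Gaussian(m.A @ g.mean + m.a, m.A @ g.cov @ m.A.T)


def fisher_line_element(g: Gaussian, dmu: np.ndarray, dsigma: np.ndarray) -> float:
    """Squared Fisher line element at ``g`` for tangent ``(dmu, dSigma)``:

        ds^2 = dmu^T Sigma^-1 dmu + 1/2 tr((Sigma^-1 dSigma)^2)
    """
    dmu = np.atleast_1d(np.asarray(dmu, dtype=float))
    dsigma = np.atleast_2d(np.asarray(dsigma, dtype=float))
    if dmu.shape[0] != g.d or dsigma.shape != (g.d, g.d):
        raise ValueError("perturbation dimension mismatch")
    if not np.allclose(dsigma, dsigma.T, atol=1e-8 * (1 + np.abs(dsigma).max())):
        raise ValueError("dSigma must be symmetric")
    c = cho_factor(g.cov)
    a = cho_solve(c, dsigma)
    return float(dmu @ cho_solve(c, dmu) + 0.5 * np.sum(a * a.T))


def bregman_fy(theta1: NaturalParam, theta2: NaturalParam) -> float:
    """Bregman divergence of the log-partition,
    ``B_F(theta1 : theta2) = F(theta1) - F(theta2) - <theta1 - theta2, grad F(theta2)>``,
    which equals the reverse KL divergence ``KL(N2 : N1)``."""
    eta2 = to_expectation(from_natural(theta2))
    gap = float(
        (theta1.theta_v - theta2.theta_v) @ eta2.eta_v
        + np.sum((theta1.theta_M - theta2.theta_M) * eta2.eta_H)
    )
    return log_partition(theta1) - log_partition(theta2) - gap


def fenchel_young(theta1: NaturalParam, eta2: ExpectationParam) -> float:
    """Fenchel-Young divergence ``Y_F(theta1 : eta2) = F(theta1) + F*(eta2)
    - <theta1, eta2>``; equals ``B_F(theta1 : theta2)`` when ``eta2 = grad F(theta2)``
    and is nonnegative for any pair (Fenchel-Young inequality)."""
    return log_partition(theta1) + dual_potential(eta2) - _inner(theta1, eta2)
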