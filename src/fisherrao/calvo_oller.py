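"""The Calvo-Oller isometric embedding of the normal manifold into the SPD cone.

A d-variate normal ``N(mu, Sigma)`` maps to the (d+1) x (d+1) SPD matrix

    f_beta(mu, Sigma) = [[Sigma + beta mu mu^T, beta mu],
                         [beta mu^T,            beta  ]],

with ``f = f_1`` an isometric (but not totally geodesic) embedding of the
Fisher-Rao normal manifold into P(d+1) equipped with the half-trace metric.
The distance between embedded matrices is the Calvo-Oller distance
``rho_CO <= rho_N``, a metric lower bound on the Fisher-Rao distance.
The orthogonal projection of any P in P(d+1) back onto the embedded
submanifold simply rescales the last row/column by ``beta = P[d,d]``, at
half-trace distance ``|log beta| / sqrt(2)`` from P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .closed_forms import delta_ratio
from .gaussian import Gaussian, validate_spd
from .spd import rho_p

__all__ = [
    "EmbeddedMatrix",
    "embed",
    "embed_general",
    "embed_sspd",
    "unembed",
    "rho_co",
    "project_to_embedding",
    "d_co",
]


@dataclass(frozen=True)
class EmbeddedMatrix:
    """A (d+1) x (d+1) SPD matrix of Calvo-Oller block form with scale beta."""

    matrix: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        M = validate_spd(self.matrix, "embedded matrix")
        beta = float(M[-1, -1])
        if not np.isclose(beta, self.beta):
            raise ValueError("bottom-right entry must equal beta")
        object.__setattr__(self, "matrix", M)
        object.__setattr__(self, "beta", beta)

    @property
    def d(self) -> int:
        return self.matrix.shape[0] - 1


def embed(g: Gaussian, beta: float = 1.0) -> EmbeddedMatrix:
    """Embed ``N(mu, Sigma)`` as an SPD matrix of size d+1.

    The determinant is preserved for beta = 1: ``|f(mu, Sigma)| = |Sigma|``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    d = g.d
    P = np.empty((d + 1, d + 1))
    P[:d, :d] = g.cov + beta * np.outer(g.mean, g.mean)
    P[:d, d] = beta * g.mean
    P[d, :d] = beta * g.mean
    P[d, d] = beta
    return EmbeddedMatrix(P, beta)


def embed_general(
    g: Gaussian, alpha: float, beta: float, gamma: float
) -> np.ndarray:
    """General embedding family
    ``g_{alpha,beta,gamma}(mu, Sigma) = |Sigma|^alpha [[Sigma + beta gamma^2 mu mu^T,
    beta gamma mu], [beta gamma mu^T, beta]]``; ``g_{0,1,1}`` is the standard
    Calvo-Oller map.  ``alpha = -1/(d+1)`` yields a unit-determinant image."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    d = g.d
    P = np.empty((d + 1, d + 1))
    P[:d, :d] = g.cov + beta * gamma**2 * np.outer(g.mean, g.mean)
    P[:d, d] = beta * gamma * g.mean
    P[d, :d] = beta * gamma * g.mean
    P[d, d] = beta
    detS = np.linalg.det(g.cov)
    return detS**alpha * P


def embed_sspd(g: Gaussian) -> np.ndarray:
    """Second isometric embedding ``|Sigma|^(-2/(d+1)) f(mu, Sigma)``,
    obtained by composing f with an elliptic isometry of the cone;
    pairwise half-trace distances agree with those of ``embed``."""
    det = np.linalg.det(g.cov)
    return det ** (-2.0 / (g.d + 1)) * embed(g).matrix


def unembed(P: np.ndarray | EmbeddedMatrix) -> tuple[Gaussian, float]:
    """Invert the embedding: read ``beta`` from the corner entry, recover
    ``mu = P[:d, d] / beta`` and ``Sigma = P[:d, :d] - beta mu mu^T``.

    Raises ``ValueError`` (via Gaussian validation) when the recovered
    covariance is not positive-definite.
    """
    M = P.matrix if isinstance(P, EmbeddedMatrix) else validate_spd(P, "P")
    beta = float(M[-1, -1])
    mu = M[:-1, -1] / beta
    cov = M[:-1, :-1] - beta * np.outer(mu, mu)
    return Gaussian(mu, cov), beta


def rho_co(g1: Gaussian, g2: Gaussian) -> float:
    """Calvo-Oller distance ``sqrt(1/2 sum_i log^2 lambda_i(P1^-1 P2))`` of the
    embedded (d+1) x (d+1) matrices: an affine-invariant metric lower bound
    on the Fisher-Rao distance."""
    if g1.d != g2.d:
        raise ValueError("dimension mismatch")
    return rho_p(embed(g1).matrix, embed(g2).matrix)


def project_to_embedding(P: np.ndarray) -> tuple[EmbeddedMatrix, float]:
    """Orthogonally project ``P`` in P(d+1) onto the embedded normal
    submanifold (beta = 1) and return the projection together with the
    half-trace distance ``|log beta| / sqrt(2)`` to it."""
    P = validate_spd(P, "P")
    beta = float(P[-1, -1])
    mu = P[:-1, -1] / beta
    cov = P[:-1, :-1] - beta * np.outer(mu, mu)
    g = Gaussian(mu, cov)
    return embed(g, 1.0), float(abs(np.log(beta)) / np.sqrt(2.0))


def d_co(g1: Gaussian, g2: Gaussian, *, sqrt: bool = False) -> float:
    """Maximal-invariant dissimilarity built from the joint invariants of the
    affine action: with ``Sigma2 Sigma1^-1 = Q diag(sbar_i^2) Q^-1`` and
    ``mubar = Q^-1 (mu2 - mu1)``,

        D_CO = 2 sum_i log^2((1 + Delta_i) / (1 - Delta_i)),
        Delta_i = Delta(0, 1; mubar_i, sbar_i).

    Symmetric, zero iff the inputs coincide.  ``Q`` is fixed to the
    canonical whitening eigenbasis ``Q = Sigma1^(1/2) Omega`` (with
    ``Sigma1^(-1/2) Sigma2 Sigma1^(-1/2) = Omega diag(sbar^2) Omega^T``),
    which makes the invariants well defined (raw eigenvectors of the
    nonsymmetric product carry arbitrary scalings) and the dissimilarity
    symmetric.  The default is the literal ``2 sum log^2`` reading;
    ``sqrt=True`` returns its square root (for d=1 the square-root variant
    reduces to a univariate hyperbolic distance in the invariants, which
    still differs from the Fisher-Rao distance).
    """
    if g1.d != g2.d:
        raise ValueError("dimension mismatch")
    w1, V1 = np.linalg.eigh(g1.cov)
    isqrt = (V1 / np.sqrt(w1)) @ V1.T
    St = isqrt @ g2.cov @ isqrt
    w, Om = np.linalg.eigh((St + St.T) / 2.0)
    if np.any(w <= 0):
        raise ValueError("Sigma2 Sigma1^-1 must have positive eigenvalues")
    mubar = Om.T @ (isqrt @ (g2.mean - g1.mean))
    sbar = np.sqrt(w)
    total = 0.0
    for mb, sb in zip(mubar, sbar):
        delta = delta_ratio(0.0, 1.0, mb, sb)
        total += np.log((1 + delta) / (1 - delta)) ** 2
    val = 2.0 * total
    return float(np.sqrt(val)) if sqrt else float(val)
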