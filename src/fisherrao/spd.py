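"""Affine-invariant geometry of the cone of symmetric positive-definite matrices.

The cone P(n) carries the trace metric ``ds^2 = 1/2 tr((P^-1 dP)^2)`` (the
scaling matches the Fisher metric of zero-mean normals).  Under this metric
the cone is a Hadamard manifold with closed-form geodesics

    gamma(P1, P2; t) = P1^(1/2) (P1^(-1/2) P2 P1^(-1/2))^t P1^(1/2)

and geodesic distance ``rho_P = (1/sqrt 2) ||Log(P1^(-1/2) P2 P1^(-1/2))||_F``.
``rho_spd`` is the same quantity without the 1/sqrt(2) factor (the unscaled
trace-metric convention).  The Hilbert projective distance
``log(lambda_max / lambda_min)`` of the relative spectrum is also provided.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, eigh, solve_triangular

from .gaussian import validate_spd

__all__ = [
    "spd_function",
    "generalized_eigvals",
    "rho_spd",
    "rho_p",
    "spd_geodesic",
    "spd_geodesic_factory",
    "hilbert_distance",
]


def spd_function(P: np.ndarray, fn: str, t: float | None = None) -> np.ndarray:
    """Apply a scalar function to the spectrum of an SPD matrix.

    ``fn`` is one of ``"power"`` (requires exponent ``t``), ``"sqrt"``,
    ``"inv-sqrt"`` or ``"log"``; eigenvectors are preserved.
    """
    P = validate_spd(P, "P")
    w, V = np.linalg.eigh(P)
    if fn == "power":
        if t is None:
            raise ValueError("fn='power' requires an exponent t")
        w = w**t
    elif fn == "sqrt":
        w = np.sqrt(w)
    elif fn == "inv-sqrt":
        w = 1.0 / np.sqrt(w)
    elif fn == "log":
        w = np.log(w)
    else:
        raise ValueError(f"unknown matrix function {fn!r}")
    return (V * w) @ V.T


def generalized_eigvals(P1: np.ndarray, P2: np.ndarray) -> np.ndarray:
    """Sorted generalized eigenvalues of ``|P2 - lambda P1| = 0``.

    These coincide with the (positive) eigenvalues of ``P1^-1 P2`` and of the
    symmetric ``P1^(-1/2) P2 P1^(-1/2)``; computed by Cholesky whitening
    ``L1^-1 P2 L1^-T`` for numerical symmetry.
    """
    P1 = validate_spd(P1, "P1")
    P2 = validate_spd(P2, "P2")
    if P1.shape != P2.shape:
        raise ValueError("size mismatch between P1 and P2")
    L = cholesky(P1, lower=True)
    W = solve_triangular(L, P2, lower=True)
    W = solve_triangular(L, W.T, lower=True)
    lam = np.linalg.eigvalsh((W + W.T) / 2.0)
    if lam[0] <= 0:
        raise ValueError("generalized eigenvalues not all positive")
    return lam


def rho_spd(P1: np.ndarray, P2: np.ndarray) -> float:
    """Unscaled affine-invariant distance ``sqrt(sum_i log^2 lambda_i(P1^-1 P2))``."""
    lam = generalized_eigvals(P1, P2)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def rho_p(P1: np.ndarray, P2: np.ndarray) -> float:
    """Geodesic distance under the half-trace metric: ``rho_spd / sqrt(2)``.

    This is the Fisher-Rao distance between zero-mean normals with
    covariances P1, P2 and the canonical distance used throughout.
    """
    return rho_spd(P1, P2) / np.sqrt(2.0)


def spd_geodesic_factory(P1: np.ndarray, P2: np.ndarray):
    """Return a callable ``t -> gamma(P1, P2; t)``.

    Uses the generalized eigendecomposition ``P2 V = P1 V diag(w)`` with
    ``V^T P1 V = I``; then ``gamma(t) = (P1 V) diag(w^t) (P1 V)^T``, which
    avoids explicit matrix square roots and is stable for ill-conditioned
    pairs.  Endpoints are reproduced exactly at t=0 and t=1 up to roundoff.
    """
    P1 = validate_spd(P1, "P1")
    P2 = validate_spd(P2, "P2")
    if P1.shape != P2.shape:
        raise ValueError("size mismatch between P1 and P2")
    w, V = eigh(P2, P1)
    if w[0] <= 0:
        raise ValueError("generalized eigenvalues not all positive")
    B = P1 @ V
    logw = np.log(w)

    def gamma(t: float) -> np.ndarray:
        G = (B * np.exp(t * logw)) @ B.T
        return (G + G.T) / 2.0

    return gamma


def spd_geodesic(
    P1: np.ndarray, P2: np.ndarray, t: float, *, extrapolate: bool = False
) -> np.ndarray:
    """Point ``gamma(P1, P2; t)`` on the Riemannian geodesic joining P1 to P2.

    ``t`` must lie in [0, 1] unless ``extrapolate=True``.
    """
    if not extrapolate and not 0.0 <= t <= 1.0:
        raise ValueError(f"t={t} outside [0, 1]; pass extrapolate=True to allow")
    return spd_geodesic_factory(P1, P2)(t)


def hilbert_distance(P1: np.ndarray, P2: np.ndarray) -> float:
    """Hilbert projective distance ``log(lambda_max / lambda_min)`` of
    ``P1^-1 P2``; zero iff P1 is a positive multiple of P2."""
    lam = generalized_eigvals(P1, P2)
    return float(np.log(lam[-1] / lam[0]))
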