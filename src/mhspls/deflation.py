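"""Matrix deflation strategies for sequential effect extraction.

After a weight-vector pair (u, v) has been estimated, the effect it
describes must be removed before the next pair can be sought. Three
interchangeable strategies are provided:

``projection``
    ``X <- X - (Xu)u'`` applied to each view with its own weight. Removes
    the component of every sample along the weight direction, so the
    deflated matrix annihilates the weight exactly; this is the default
    because it actively pushes successive (pseudo-)sparse weight pairs
    towards orthogonality.
``pls``
    The classical PLS regression residual: scores ``xi = Xu/(u'u)`` and
    loadings ``a = X'xi/(xi'xi)``, then ``X <- X - xi a'`` (likewise for Y
    with v). Columns of the residual are orthogonal to the score vector.
``hotelling``
    ``C <- C - (u'Cv) u v'`` applied to the cross-covariance matrix rather
    than the data; provided for covariance-only workflows. It cannot be
    combined with hold-out evaluation (there are no deflated data matrices
    to project), and the framework refuses that combination.
"""

from __future__ import annotations

import math

import numpy as np

from .core import DegenerateScoreError

__all__ = [
    "DEFLATION_METHODS",
    "projection_deflate",
    "pls_deflate",
    "hotelling_deflate",
]

DEFLATION_METHODS = ("projection", "pls", "hotelling")


def projection_deflate(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Return ``X(I - ww') = X - (Xw)w'`` for a unit vector ``w``.

    The deflated matrix satisfies ``X_deflated @ w = 0`` and the map is
    idempotent (deflating twice with the same ``w`` changes nothing).
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float).ravel()
    if X.shape[1] != w.size:
        raise ValueError("column count of X must equal the length of w")
    if abs(math.sqrt(float(w @ w)) - 1.0) > 1e-6:
        raise ValueError("projection deflation requires a unit-l2 weight vector")
    return X - np.outer(X @ w, w)


def pls_deflate(
    X: np.ndarray, Y: np.ndarray, u: np.ndarray, v: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Classical PLS regression deflation of both views.

    Computes scores ``xi = Xu/(u'u)`` and ``omega = Yv/(v'v)``, regresses
    each view on its score to get loadings ``a = X'xi/(xi'xi)`` and
    ``b = Y'omega/(omega'omega)``, and returns the residuals
    ``X - xi a'`` and ``Y - omega b'``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    xi = X @ u / float(u @ u)
    omega = Y @ v / float(v @ v)
    ss_xi = float(xi @ xi)
    ss_om = float(omega @ omega)
    if ss_xi <= 0.0 or ss_om <= 0.0:
        raise DegenerateScoreError("a latent score vector is identically zero")
    a = X.T @ xi / ss_xi
    b = Y.T @ omega / ss_om
    return X - np.outer(xi, a), Y - np.outer(omega, b)


def hotelling_deflate(C: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Hotelling deflation ``C - (u'Cv) u v'`` of a cross-covariance matrix."""
    C = np.asarray(C, dtype=float)
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if C.shape != (u.size, v.size):
        raise ValueError("dimensions of C, u and v do not match")
    d = float(u @ C @ v)
    return C - d * np.outer(u, v)
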