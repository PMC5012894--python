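"""Rank-1 PLS and sparse PLS (SPLS) weight-pair estimation.

Given two views ``X`` (n x p) and ``Y`` (n x q), PLS finds unit weight
vectors ``u`` and ``v`` maximising the covariance of the projections,

    max  u' X' Y v   s.t.  ||u||_2 = ||v||_2 = 1,

whose solution is the leading singular-vector pair of the cross-covariance
matrix ``C = X' Y``. SPLS additionally imposes l1 budgets ``||u||_1 <= c_u``
and ``||v||_1 <= c_v`` (with ``c >= 1`` so at least one feature always
survives), producing sparse, interpretable weight pairs. The solver
alternates the updates ``u <- Cv`` and ``v <- C'u``, each followed by a
soft-thresholded projection onto the intersection of the l2 unit sphere and
the l1 ball, starting from the leading SVD pair of ``C``.

The per-update subproblem ``max w'a s.t. ||w||_2 <= 1, ||w||_1 <= c`` is
solved by ``sparse_project``: soft-threshold ``a`` at some level Δ and
renormalise, where Δ = 0 if the plain renormalised vector already satisfies
the budget, and otherwise Δ is the unique level at which the l1 norm of the
renormalised thresholded vector equals ``c``. Because that l1 norm is a
continuous, monotone, piecewise algebraic function of Δ (the support only
changes at the sorted magnitudes of the input), the level is found exactly:
a monotone scan over the sorted breakpoints locates the active segment and
a closed-form quadratic solve gives Δ inside it.

The two numerical kernels (the projection and the alternating loop) are
written in loop style and JIT-compiled with numba when available; without
numba the same functions run as plain Python.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly by every test
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateInputError",
    "DegenerateScoreError",
    "InvalidStateError",
    "SparsityPair",
    "WeightPair",
    "soft_threshold",
    "sparse_project",
    "cross_covariance",
    "pls_rank1",
    "spls_fit",
    "inactive_sparsity",
]


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. an all-zero cross-covariance)."""


class DegenerateScoreError(DegenerateInputError):
    """A latent score vector needed for deflation is identically zero."""


class InvalidStateError(RuntimeError):
    """An operation was called in a state its contract forbids."""


@dataclass(frozen=True)
class SparsityPair:
    """l1 budgets for the two weight vectors.

    Both budgets must be >= 1; values at or above sqrt(dim) leave the l1
    constraint inactive, because a unit-l2 vector of length d satisfies
    ||w||_1 <= sqrt(d).
    """

    c_u: float
    c_v: float

    def __post_init__(self) -> None:
        if self.c_u < 1.0 or self.c_v < 1.0:
            raise ValueError("l1 budgets c_u and c_v must both be >= 1")


@dataclass
class WeightPair:
    """A fitted weight-vector pair describing one associative effect."""

    u: np.ndarray
    v: np.ndarray
    effect_index: int = 1
    sparsity: SparsityPair | None = None
    n_iter: int = 0
    converged: bool = True

    @property
    def n_nonzero_u(self) -> int:
        return int(np.count_nonzero(self.u))

    @property
    def n_nonzero_v(self) -> int:
        return int(np.count_nonzero(self.v))


def soft_threshold(a: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise soft-thresholding ``sgn(a) * max(|a| - lam, 0)``.

    Shrinks magnitudes by ``lam`` and zeroes entries with ``|a| <= lam``;
    never flips signs.
    """
    if lam < 0:
        raise ValueError("soft-threshold level must be non-negative")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


@njit(cache=True)
def _project(w: np.ndarray, c: float):  # pragma: no cover - jit-compiled
    """Kernel behind :func:`sparse_project`; returns ``(vector, status)``.

    status 0: ok; 1: degenerate all-zero input.
    """
    p = w.shape[0]
    out = np.zeros(p)
    nrm2 = 0.0
    l1 = 0.0
    for i in range(p):
        ai = abs(w[i])
        nrm2 += ai * ai
        l1 += ai
    if nrm2 == 0.0:
        return out, 1
    nrm = math.sqrt(nrm2)
    if l1 <= (c + 1e-9) * nrm:
        for i in range(p):
            out[i] = w[i] / nrm
        return out, 0
    a = np.empty(p)
    for i in range(p):
        a[i] = abs(w[i])
    s = np.sort(a)[::-1]
    tie_thr = s[0] * (1.0 - 1e-12)
    n_tied = 0
    for i in range(p):
        if s[i] >= tie_thr:
            n_tied += 1
        else:
            break
    if c < math.sqrt(n_tied) - 1e-9:
        # budget unattainable by thresholding (exact ties at the maximum):
        # keep the first tied entry at magnitude one
        for i in range(p):
            if a[i] >= tie_thr:
                out[i] = 1.0 if w[i] > 0.0 else -1.0
                return out, 0
    # locate the segment [s[k], s[k-1]) whose renormalised l1 norm brackets c;
    # the norm at the segment's lower edge is non-decreasing in k
    S1 = 0.0
    S2 = 0.0
    kstar = p
    lo = 0.0
    hi = s[0]
    for k in range(1, p + 1):
        sk = s[k - 1]
        S1 += sk
        S2 += sk * sk
        lam_lo = s[k] if k < p else 0.0
        l1k = S1 - k * lam_lo
        l2sq = S2 - 2.0 * lam_lo * S1 + k * lam_lo * lam_lo
        if l2sq < 1e-300:
            l2sq = 1e-300
        if l1k / math.sqrt(l2sq) >= c:
            kstar = k
            lo = lam_lo
            hi = sk
            break
    # closed-form root of (S1 - kΔ)^2 = c^2 (S2 - 2ΔS1 + kΔ^2) in the segment
    kk = float(kstar)
    A = kk * (kk - c * c)
    B = -2.0 * S1 * (kk - c * c)
    Cq = S1 * S1 - c * c * S2
    if abs(A) < 1e-30:
        lam = lo  # the renormalised l1 norm is constant over this segment
    else:
        disc = B * B - 4.0 * A * Cq
        if disc < 0.0:
            disc = 0.0
        sq = math.sqrt(disc)
        r1 = (-B - sq) / (2.0 * A)
        r2 = (-B + sq) / (2.0 * A)
        mid = 0.5 * (lo + hi)
        ok1 = (lo - 1e-12) <= r1 <= (hi + 1e-12)
        ok2 = (lo - 1e-12) <= r2 <= (hi + 1e-12)
        if ok1 and (not ok2 or abs(r1 - mid) <= abs(r2 - mid)):
            lam = r1
        elif ok2:
            lam = r2
        else:
            lam = r1 if abs(r1 - mid) <= abs(r2 - mid) else r2
        if lam < lo:
            lam = lo
        elif lam > hi:
            lam = hi
    nrm2 = 0.0
    for i in range(p):
        wi = w[i]
        if wi > lam:
            out[i] = wi - lam
        elif wi < -lam:
            out[i] = wi + lam
        else:
            out[i] = 0.0
        nrm2 += out[i] * out[i]
    if nrm2 == 0.0:
        # floating-point collapse: fall back to the first maximal entry
        for i in range(p):
            if a[i] >= tie_thr:
                out[i] = 1.0 if w[i] > 0.0 else -1.0
                return out, 0
    nrm = math.sqrt(nrm2)
    for i in range(p):
        out[i] /= nrm
    return out, 0


@njit(cache=True)
def _spls_kernel(
    C: np.ndarray,
    Ct: np.ndarray,
    c_u: float,
    c_v: float,
    v0: np.ndarray,
    tol: float,
    max_iter: int,
):  # pragma: no cover - jit-compiled
    """Alternating soft-thresholded updates; returns (u, v, it, converged, status)."""
    p, q = C.shape
    v = v0 / math.sqrt(float(np.dot(v0, v0)))
    u = np.zeros(p)
    converged = 0
    it = 0
    first = True
    for it in range(1, max_iter + 1):
        u_new, st = _project(np.dot(C, v), c_u)
        if st != 0:
            return u, v, it, 0, 1
        v_new, st = _project(np.dot(Ct, u_new), c_v)
        if st != 0:
            return u, v, it, 0, 1
        if first:
            u, v = u_new, v_new
            first = False
            continue
        if float(np.dot(u_new, u)) + float(np.dot(v_new, v)) < 0.0:
            u_new, v_new = -u_new, -v_new  # joint sign alignment
        delta = 0.0
        for i in range(p):
            d = abs(u_new[i] - u[i])
            if d > delta:
                delta = d
        for j in range(q):
            d = abs(v_new[j] - v[j])
            if d > delta:
                delta = d
        u, v = u_new, v_new
        if delta <= tol:
            converged = 1
            break
    return u, v, it, converged, 0


def sparse_project(w: np.ndarray, c: float) -> np.ndarray:
    """Project onto the unit l2 sphere intersected with the l1 ball of radius ``c``.

    Returns ``S(w, Δ) / ||S(w, Δ)||_2`` where Δ = 0 whenever the plain
    renormalised vector already satisfies ``||.||_1 <= c`` and otherwise Δ is
    the exact positive level at which the renormalised vector's l1 norm
    equals ``c``. When the budget is unattainable because the largest
    magnitudes are exactly tied (the renormalised l1 norm cannot drop below
    sqrt(#ties)), the tied entry with the lowest index is kept at magnitude
    one — a deterministic fallback that preserves the at-least-one-feature
    guarantee.
    """
    w = np.ascontiguousarray(w, dtype=float).ravel()
    if c < 1.0:
        raise ValueError("l1 budget c must be >= 1")
    out, status = _project(w, float(c))
    if status != 0:
        raise DegenerateInputError("cannot sparse-project an all-zero vector")
    return out


def cross_covariance(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Cross-covariance matrix ``C = X' Y`` (p x q) of two matched views."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    return X.T @ Y


def _svd_leading(C: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    U, sv, Vt = np.linalg.svd(C, full_matrices=False)
    return U[:, 0], Vt[0], float(sv[0])


def _init_v(C: np.ndarray) -> np.ndarray:
    """Leading right singular direction of C, via the small-side Gram matrix.

    Used to initialise the alternating solver, so the (squared) conditioning
    of the eigen route is irrelevant; it is much cheaper than a full SVD
    when one side is wide.
    """
    p, q = C.shape
    if q <= p:
        return np.linalg.eigh(C.T @ C)[1][:, -1]
    u = np.linalg.eigh(C @ C.T)[1][:, -1]
    v = C.T @ u
    n = math.sqrt(float(v @ v))
    if n == 0.0:
        raise DegenerateInputError("cross-covariance matrix is identically zero")
    return v / n


def _fix_sign(u: np.ndarray, v: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # orient so the captured covariance u'Cv is non-negative, then pin the
    # joint sign (which leaves u'Cv unchanged) via the largest |u| entry
    if float(u @ C @ v) < 0.0:
        v = -v
    i = int(np.argmax(np.abs(u)))
    if u[i] < 0.0:
        u, v = -u, -v
    return u, v


def _pls_rank1_cov(C: np.ndarray, effect_index: int = 1) -> WeightPair:
    if not np.any(C):
        raise DegenerateInputError("cross-covariance matrix is identically zero")
    u, v, _ = _svd_leading(C)
    u, v = _fix_sign(u, v, C)
    return WeightPair(u=u, v=v, effect_index=effect_index, sparsity=None, n_iter=1, converged=True)


def pls_rank1(data) -> WeightPair:
    """Leading singular-vector pair of ``X'Y``: the plain (non-sparse) PLS solution."""
    return _pls_rank1_cov(cross_covariance(data.X, data.Y))


def _spls_cov(
    C: np.ndarray,
    sparsity: SparsityPair,
    tol: float = 1e-6,
    max_iter: int = 500,
    v0: np.ndarray | None = None,
    effect_index: int = 1,
) -> WeightPair:
    """Alternating soft-thresholded updates on a precomputed cross-covariance."""
    C = np.ascontiguousarray(C, dtype=float)
    if not np.any(C):
        raise DegenerateInputError("cross-covariance matrix is identically zero")
    if v0 is None:
        v0 = _init_v(C)
    u, v, it, converged, status = _spls_kernel(
        C,
        np.ascontiguousarray(C.T),
        float(sparsity.c_u),
        float(sparsity.c_v),
        np.ascontiguousarray(v0, dtype=float),
        float(tol),
        int(max_iter),
    )
    if status != 0:
        raise DegenerateInputError("an update vector vanished: degenerate cross-covariance")
    if not converged:
        warnings.warn(
            f"SPLS did not converge within {max_iter} iterations "
            f"(c_u={sparsity.c_u:.3g}, c_v={sparsity.c_v:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    u, v = _fix_sign(u, v, C)
    return WeightPair(
        u=u, v=v, effect_index=effect_index, sparsity=sparsity, n_iter=it,
        converged=bool(converged),
    )


def spls_fit(data, sparsity: SparsityPair, tol: float = 1e-6, max_iter: int = 500) -> WeightPair:
    """Fit one sparse weight-vector pair on a :class:`~mhspls.data.TwoViewDataset`.

    Alternates ``u <- sparse_project(Cv, c_u)`` and
    ``v <- sparse_project(C'u, c_v)`` from the leading-SVD initialisation of
    ``v`` until the largest elementwise change (after joint sign alignment)
    drops to ``tol``, or ``max_iter`` is reached (in which case the pair is
    returned with ``converged=False`` and a warning).
    """
    C = cross_covariance(data.X, data.Y)
    return _spls_cov(C, sparsity, tol=tol, max_iter=max_iter)


def inactive_sparsity(p: int, q: int) -> SparsityPair:
    """Budgets at the upper end of the admissible range, where the l1 constraint
    cannot bind (``||w||_1 <= sqrt(dim)`` for unit-l2 vectors)."""
    return SparsityPair(math.sqrt(p), math.sqrt(q))
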