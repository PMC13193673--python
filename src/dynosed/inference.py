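"""Regularized solution of A theta = b with identifiability and sensitivity.

Existence of an exactly-consistent parameter vector is equivalent to
b lying in range(A); uniqueness to full column rank.  The practical solver
is ridge regression theta = (A^T A + lambda I)^{-1} A^T b.  Parameter-wise
"freeness" -- the diagonal of the inverse regularized Gram matrix
H = A^T A + lambda I -- quantifies how weakly each parameter is constrained
by the data: a freeness near 1/lambda flags an effectively free direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .local_route import LinearSystem


class RankError(np.linalg.LinAlgError):
    """lambda = 0 requested for a rank-deficient system."""


@dataclass
class SolveResult:
    """Ridge solution together with its Gram-based sensitivity diagnostics."""

    theta_hat: np.ndarray
    lam: float
    H: np.ndarray
    freeness_raw: np.ndarray
    freeness_norm: np.ndarray
    residual_norm: float
    route: str = ""


@dataclass
class IdentifiabilityReport:
    """Rank condition and range membership of an assembled system."""

    rank: int
    singular_values: np.ndarray
    existence_residual: float
    exists: bool
    unique: bool
    tol: float
    null_directions: Optional[np.ndarray] = None  # right singular vectors of sigma ~ 0


def _svd(sys: LinearSystem):
    return np.linalg.svd(sys.A, full_matrices=False)


def ridge_solve(
    sys: LinearSystem, lam: float, allow_pinv: bool = False
) -> SolveResult:
    """Solve min ||A theta - b||^2 + lambda ||theta||^2 via the SVD.

    theta = (A^T A + lambda I)^{-1} A^T b.  With lambda = 0 a rank-deficient
    A raises :class:`RankError` unless ``allow_pinv`` selects the
    minimum-norm (pseudo-inverse) solution.  The same SVD yields the Gram
    matrix H = A^T A + lambda I and the freeness diagnostics (diag of
    H^{-1}, and its max-normalized form); freeness requires lambda > 0 or a
    full-rank A.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    Uu, sv, Vt = _svd(sys)
    n = sys.n_params
    rank = int(np.sum(sv > 1e-12 * max(sv[0], 1e-300)))
    if lam == 0.0 and rank < n:
        if not allow_pinv:
            raise RankError(
                f"A has rank {rank} < n = {n} and lambda = 0; pass allow_pinv=True "
                "for the minimum-norm solution or use lambda > 0"
            )
        filt = np.where(sv > 1e-12 * sv[0], 1.0 / np.where(sv > 0, sv, 1.0), 0.0)
        theta = Vt.T @ (filt * (Uu.T @ sys.b))
    else:
        denom = sv**2 + lam
        theta = Vt.T @ ((sv / denom) * (Uu.T @ sys.b))
    H = sys.A.T @ sys.A + lam * np.eye(n)
    try:
        free_raw, free_norm = freeness(sys, lam)
    except RankError:
        free_raw = np.full(n, np.nan)
        free_norm = np.full(n, np.nan)
    resid = float(np.linalg.norm(sys.A @ theta - sys.b))
    return SolveResult(
        theta_hat=theta, lam=lam, H=H, freeness_raw=free_raw,
        freeness_norm=free_norm, residual_norm=resid, route=sys.route,
    )


def freeness(sys: LinearSystem, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Parameter-wise freeness: diag((A^T A + lambda I)^{-1}), raw and max-normalized.

    Small freeness marks a tightly constrained parameter; a parameter whose
    basis direction is absent from the data attains the maximum 1/lambda.
    """
    _, sv, Vt = _svd(sys)
    n = sys.n_params
    if lam <= 0:
        rank = int(np.sum(sv > 1e-12 * max(sv[0], 1e-300)))
        if rank < n:
            raise RankError("freeness at lambda = 0 requires a full-rank system")
        if lam < 0:
            raise ValueError("lambda must be nonnegative")
    sv_full = np.zeros(n)
    sv_full[: sv.shape[0]] = sv
    inv_eig = 1.0 / (sv_full**2 + lam)
    V_full = _complete_basis(Vt, n)
    raw = np.einsum("ji,j,ji->i", V_full, inv_eig, V_full)
    return raw, raw / np.max(raw)


def _complete_basis(Vt: np.ndarray, n: int) -> np.ndarray:
    """Extend the rows of V^T to an orthonormal basis of R^n (for M < n)."""
    if Vt.shape[0] == n:
        return Vt
    basis = list(Vt)
    for e in np.eye(n):
        v = e - sum((e @ bb) * bb for bb in basis)
        nv = np.linalg.norm(v)
        if nv > 1e-10:
            basis.append(v / nv)
        if len(basis) == n:
            break
    return np.array(basis[:n])


def identifiability(
    sys: LinearSystem, tol: float = 1e-8, existence_tol: Optional[float] = None
) -> IdentifiabilityReport:
    """Rank condition: a consistent theta exists iff b is in range(A); unique iff rank(A) = n.

    ``rank`` counts singular values above tol * sigma_max; ``exists`` holds
    when the relative residual of projecting b onto range(A) is at most
    ``existence_tol`` (default: ``tol``).  The exact rank condition applies
    to exact scores / infinite data; systems assembled from finite samples
    carry Monte-Carlo noise in b, so their consistency check needs a
    commensurately looser existence tolerance.  Near-null right singular
    vectors are reported as the unidentifiable directions.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if existence_tol is None:
        existence_tol = tol
    if sys.A.size == 0:
        raise ValueError("empty linear system")
    Uu, sv, Vt = np.linalg.svd(sys.A, full_matrices=False)
    smax = sv[0] if sv.size else 0.0
    rank = int(np.sum(sv > tol * max(smax, 1e-300)))
    proj = Uu[:, :rank] @ (Uu[:, :rank].T @ sys.b)
    bnorm = np.linalg.norm(sys.b)
    resid = float(np.linalg.norm(sys.b - proj) / max(bnorm, 1e-300))
    if bnorm == 0.0:
        resid = 0.0  # b = 0 always lies in range(A)
    exists = resid <= existence_tol
    unique = rank == sys.n_params
    null_dirs = Vt[rank:].T if rank < Vt.shape[0] else None
    return IdentifiabilityReport(
        rank=rank, singular_values=sv, existence_residual=resid,
        exists=exists, unique=unique, tol=tol, null_directions=null_dirs,
    )
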