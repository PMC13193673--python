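"""Global kernel-Stein-discrepancy identification route.

For globally (if sparsely) sampled steady-state data the Fokker-Planck
residual is enforced in the weak sense E_p[A_theta phi] = 0 over the unit
ball of an RBF reproducing-kernel Hilbert space, where the diffusion-Stein
operator is A_theta phi = f_theta^T grad phi + Tr(D hess phi).  Random
Fourier features z_r(x) = sqrt(2/m) cos(w_r^T x + c_r) turn the quadratic
KSD into the squared norm of a mean Stein-feature vector, evaluated in
O(N m); the exact O(N^2) double-Stein form is kept as an oracle.  For
affine drifts the mean feature is linear in theta and the route again
reduces to A theta = b.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.optimize

from .local_route import LinearSystem, OptimizerOptions
from .models import AffineDrift, DiffusionSpec, ParametricDrift
from .simulate import NonSeqDataset


class OracleSizeError(RuntimeError):
    """The exact O(N^2) KSD was asked for too many samples."""


@dataclass
class RFFBasis:
    """A sampled random Fourier feature basis for the RBF kernel.

    Frequencies are i.i.d. N(0, I / lengthscale^2) rows and phases uniform
    on [0, 2 pi); the feature map z_r(x) = sqrt(2/m) cos(w_r^T x + c_r)
    satisfies E[z(x)^T z(y)] = exp(-||x - y||^2 / (2 lengthscale^2)).
    """

    m: int
    omega: np.ndarray
    c: np.ndarray
    lengthscale: Union[float, np.ndarray]
    seed: int = 0

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.c = np.asarray(self.c, dtype=float).ravel()
        if self.omega.ndim != 2 or self.omega.shape[0] != self.m:
            raise ValueError("omega must be an (m, d) matrix")
        if self.c.shape[0] != self.m:
            raise ValueError("phase vector length must equal the feature count")
        if np.any(self.c < 0) or np.any(self.c >= 2 * np.pi):
            raise ValueError("phases must lie in [0, 2 pi)")

    @property
    def dim(self) -> int:
        return self.omega.shape[1]

    def features(self, X: np.ndarray) -> np.ndarray:
        """z(x) for a batch: shape (N, m)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.sqrt(2.0 / self.m) * np.cos(X @ self.omega.T + self.c)


def sample_rff(
    m: int, d: int, lengthscale: Union[float, np.ndarray], seed: int = 0
) -> RFFBasis:
    """Draw an RFF basis: omega ~ N(0, diag(1/lengthscale^2)), phases ~ U[0, 2 pi).

    ``lengthscale`` may be a scalar (isotropic RBF kernel) or a length-d
    vector of per-coordinate lengthscales (anisotropic RBF), useful when
    state coordinates live on very different scales.
    """
    ell = np.asarray(lengthscale, dtype=float)
    if m < 1 or np.any(ell <= 0):
        raise ValueError("m >= 1 and lengthscale > 0 required")
    rng = np.random.default_rng(seed)
    omega = rng.standard_normal((m, d)) / ell
    c = rng.uniform(0.0, 2.0 * np.pi, size=m)
    return RFFBasis(m=m, omega=omega, c=c, lengthscale=lengthscale, seed=seed)


def sample_rff_multiscale(
    m: int,
    d: int,
    lengthscales: Sequence[Union[float, np.ndarray]],
    seed: int = 0,
) -> RFFBasis:
    """RFF basis for a uniform mixture of RBF kernels at several lengthscales.

    The m features are split evenly across the lengthscales; the resulting
    feature inner product approximates the average of the component RBF
    kernels, which spreads test-function sensitivity across scales and
    improves the conditioning of the assembled affine system.
    """
    if not lengthscales:
        raise ValueError("need at least one lengthscale")
    rng = np.random.default_rng(seed)
    per = m // len(lengthscales)
    if per < 1:
        raise ValueError("m must be at least the number of lengthscales")
    blocks = []
    for ell in lengthscales:
        ell = np.asarray(ell, dtype=float)
        if np.any(ell <= 0):
            raise ValueError("lengthscales must be positive")
        blocks.append(rng.standard_normal((per, d)) / ell)
    omega = np.vstack(blocks)
    m_eff = omega.shape[0]
    c = rng.uniform(0.0, 2.0 * np.pi, size=m_eff)
    return RFFBasis(m=m_eff, omega=omega, c=c, lengthscale=lengthscales[0], seed=seed)


def median_lengthscale(
    data: Union[NonSeqDataset, np.ndarray], max_rows: int = 500, seed: int = 0
) -> float:
    """Median pairwise distance of a subsample (the standard RBF heuristic)."""
    X = data.X if isinstance(data, NonSeqDataset) else np.atleast_2d(data)
    if X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(X.shape[0], size=max_rows, replace=False)]
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(X.shape[0], 1)
    return float(np.median(dist[iu]))


def per_dim_lengthscale(
    data: Union[NonSeqDataset, np.ndarray], scale: float = 2.0
) -> np.ndarray:
    """Per-coordinate lengthscales: ``scale`` times each coordinate's spread.

    Suits anisotropic clouds whose coordinates span different ranges (an
    isotropic median distance is then dominated by the widest directions and
    under-resolves the narrow ones)."""
    X = data.X if isinstance(data, NonSeqDataset) else np.atleast_2d(data)
    sd = X.std(axis=0)
    if np.any(sd <= 0):
        raise ValueError("degenerate coordinate with zero spread")
    return scale * sd


def _quad_form(basis: RFFBasis, diffusion: DiffusionSpec, X: np.ndarray) -> np.ndarray:
    """w_r^T D w_r per feature; shape (m,) for constant D, (N, m) otherwise."""
    if diffusion.is_constant:
        return np.einsum("rd,de,re->r", basis.omega, diffusion.constant_D, basis.omega)
    Dx = np.stack([diffusion.D(x) for x in X])  # (N, d, d)
    return np.einsum("rd,nde,re->nr", basis.omega, Dx, basis.omega)


def stein_feature(
    x: np.ndarray,
    theta: np.ndarray,
    basis: RFFBasis,
    drift: ParametricDrift,
    diffusion: DiffusionSpec,
) -> np.ndarray:
    """Stein feature vector g(x; theta) of a single state.

    g_r = -sqrt(2/m) [ sin(w_r^T x + c_r) w_r^T f_theta(x)
                       + cos(w_r^T x + c_r) w_r^T D w_r ],
    i.e. the diffusion-Stein operator applied to each cosine feature
    (D evaluated at x when state-dependent).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != basis.dim:
        raise ValueError(f"state has length {x.size}, expected {basis.dim}")
    t = basis.omega @ x + basis.c
    f = np.asarray(drift.drift(x, theta), dtype=float).ravel()
    quad = _quad_form(basis, diffusion, x[None, :])
    quad = quad if diffusion.is_constant else quad[0]
    return -np.sqrt(2.0 / basis.m) * (np.sin(t) * (basis.omega @ f) + np.cos(t) * quad)


def mean_stein_feature(
    data: Union[NonSeqDataset, np.ndarray],
    theta: np.ndarray,
    basis: RFFBasis,
    drift: ParametricDrift,
    diffusion: DiffusionSpec,
    chunk: int = 4096,
) -> np.ndarray:
    """Sample mean of the Stein feature over the data; O(N m), chunked."""
    X = data.X if isinstance(data, NonSeqDataset) else np.atleast_2d(np.asarray(data, float))
    N = X.shape[0]
    if N == 0:
        raise ValueError("data is empty")
    acc = np.zeros(basis.m)
    for lo in range(0, N, chunk):
        Xc = X[lo : lo + chunk]
        t = Xc @ basis.omega.T + basis.c  # (nc, m)
        f = np.asarray(drift.drift(Xc, theta), dtype=float)  # (nc, d)
        quad = _quad_form(basis, diffusion, Xc)
        acc += (np.sin(t) * (f @ basis.omega.T) + np.cos(t) * quad).sum(0)
    return -np.sqrt(2.0 / basis.m) * acc / N


def global_loss(
    data: Union[NonSeqDataset, np.ndarray],
    theta: np.ndarray,
    basis: RFFBasis,
    drift: ParametricDrift,
    diffusion: DiffusionSpec,
) -> float:
    """Linear-time KSD loss: squared norm of the mean Stein feature."""
    g = mean_stein_feature(data, theta, basis, drift, diffusion)
    return float(g @ g)


def exact_ksd(
    data: Union[NonSeqDataset, np.ndarray],
    theta: np.ndarray,
    lengthscale: float,
    drift: ParametricDrift,
    diffusion: DiffusionSpec,
    max_n: int = 2000,
) -> float:
    """Exact O(N^2) kernel Stein discrepancy with the RBF kernel (oracle).

    Computes (1/N^2) sum_ij A_x A_y k(x_i, x_j) from closed-form derivatives
    of k(x, y) = exp(-||x - y||^2 / (2 l^2)) up to the mixed fourth
    derivative required by the trace-trace term.  Constant diffusion only;
    intended as a small-N oracle for the RFF loss.
    """
    X = data.X if isinstance(data, NonSeqDataset) else np.atleast_2d(np.asarray(data, float))
    N = X.shape[0]
    if N > max_n:
        raise OracleSizeError(
            f"exact KSD is O(N^2); N={N} exceeds the oracle cap {max_n} -- "
            "use global_loss with random Fourier features instead"
        )
    if not diffusion.is_constant:
        raise NotImplementedError("exact KSD oracle supports constant diffusion only")
    D = diffusion.constant_D
    g = 1.0 / lengthscale**2
    F = np.asarray(drift.drift(X, theta), dtype=float)  # (N, d)
    U = X[:, None, :] - X[None, :, :]  # (N, N, d), u = x - y
    k = np.exp(-g / 2.0 * (U**2).sum(-1))  # (N, N)
    trD = float(np.trace(D))
    trD2 = float(np.trace(D @ D))
    DU = U @ D  # (N, N, d): D u (D symmetric)
    alpha = (U * DU).sum(-1)  # u^T D u
    uD2u = (DU * DU).sum(-1)  # u^T D^2 u
    fx_u = np.einsum("id,ijd->ij", F, U)  # f(x_i) . u_ij
    fy_u = np.einsum("jd,ijd->ij", F, U)  # f(x_j) . u_ij
    fx_fy = F @ F.T
    fx_Du = np.einsum("id,ijd->ij", F, DU)
    fy_Du = np.einsum("jd,ijd->ij", F, DU)
    term1 = g * k * (fx_fy - g * fx_u * fy_u)
    term2 = g**2 * k * (2.0 * fx_Du - fx_u * (g * alpha - trD))
    term3 = g**2 * k * (-2.0 * fy_Du + fy_u * (g * alpha - trD))
    term4 = g**2 * k * (
        (g * alpha - trD) ** 2 + 2.0 * trD2 - 4.0 * g * uD2u
    )
    return float((term1 + term2 + term3 + term4).sum()) / N**2


def assemble_global_system(
    data: Union[NonSeqDataset, np.ndarray],
    basis: RFFBasis,
    aff: AffineDrift,
    diffusion: DiffusionSpec,
    chunk: int = 2048,
    single_precision: bool = False,
) -> LinearSystem:
    """Assemble the global-route system A theta = b from an affine drift.

    Row r of A is the sample mean of sin(w_r^T x + c_r) w_r^T U(x); entry r
    of b is minus the sample mean of sin(w_r^T x + c_r) w_r^T v(x) +
    cos(w_r^T x + c_r) w_r^T D w_r, so that the mean Stein feature equals
    -sqrt(2/m) (A theta - b) and the loss equals (2/m) ||A theta - b||^2.

    ``single_precision`` evaluates the trigonometric feature maps in
    float32 (roughly twice as fast for large N x m); sums are still
    accumulated in float64, so entries carry a relative error ~1e-7 --
    negligible against the O(1/sqrt(N)) Monte-Carlo noise, but do not use
    it where 1e-10 identities are asserted.
    """
    X = data.X if isinstance(data, NonSeqDataset) else np.atleast_2d(np.asarray(data, float))
    N = X.shape[0]
    if N == 0:
        raise ValueError("data is empty")
    m, n = basis.m, aff.dim_params
    A = np.zeros((m, n))
    b = np.zeros(m)
    ftype = np.float32 if single_precision else np.float64
    omega_f = basis.omega.T.astype(ftype)
    c_f = basis.c.astype(ftype)
    for lo in range(0, N, chunk):
        Xc = X[lo : lo + chunk]
        t = Xc.astype(ftype) @ omega_f + c_f  # (nc, m)
        sin_t, cos_t = np.sin(t), np.cos(t)
        vc = np.asarray(aff.v(Xc), dtype=float).astype(ftype)  # (nc, d)
        if aff.structure is not None:
            # factored columns u_q(x) e_g: row sums reduce to one (m, q) matmul
            Bsc = np.asarray(aff.structure.scalar_basis(Xc), dtype=float).astype(ftype)
            SB = (sin_t.T @ Bsc).astype(np.float64)  # (m, q)
            for kcol, (g, q) in enumerate(aff.structure.columns):
                A[:, kcol] += basis.omega[:, g] * SB[:, q]
        else:
            Uc = np.asarray(aff.U(Xc), dtype=float)  # (nc, d, n)
            for kcol in range(n):
                A[:, kcol] += (sin_t * (Uc[:, :, kcol].astype(ftype) @ omega_f)).sum(0, dtype=np.float64)
        quad = _quad_form(basis, diffusion, Xc)
        if diffusion.is_constant:
            b -= (sin_t * (vc @ omega_f)).sum(0, dtype=np.float64) + cos_t.sum(0, dtype=np.float64) * quad
        else:
            b -= (sin_t * (vc @ omega_f)).sum(0, dtype=np.float64) + (cos_t * quad).sum(0, dtype=np.float64)
    A /= N
    b /= N
    meta = {
        "n_samples": N,
        "n_features": m,
        "lengthscale": basis.lengthscale,
        "basis_seed": basis.seed,
        "model": aff.name,
    }
    return LinearSystem(A, b, route="global", meta=meta)


def minimize_global(
    data: Union[NonSeqDataset, np.ndarray],
    basis: RFFBasis,
    drift: ParametricDrift,
    diffusion: DiffusionSpec,
    theta0: np.ndarray,
    opts: Optional[OptimizerOptions] = None,
) -> np.ndarray:
    """Minimize the global KSD loss by deterministic quasi-Newton (BFGS).

    For affine drifts this matches the lambda = 0 solve of the assembled
    system (convex quadratic with an analytic gradient); otherwise central
    finite differences supply the gradient.
    """
    opts = opts or OptimizerOptions()
    theta0 = np.asarray(theta0, dtype=float).ravel()
    if isinstance(drift, AffineDrift):
        sys_ = assemble_global_system(data, basis, drift, diffusion)
        A, b = sys_.A, sys_.b
        scale = 2.0 / basis.m

        def loss(th: np.ndarray) -> float:
            r = A @ th - b
            return scale * float(r @ r)

        def jacfun(th: np.ndarray) -> np.ndarray:
            return 2.0 * scale * A.T @ (A @ th - b)

    else:

        def loss(th: np.ndarray) -> float:
            return global_loss(data, th, basis, drift, diffusion)

        def jacfun(th: np.ndarray) -> np.ndarray:
            gvec = np.empty_like(th)
            for j in range(th.size):
                h = opts.fd_step * (1.0 + abs(th[j]))
                tp, tm = th.copy(), th.copy()
                tp[j] += h
                tm[j] -= h
                gvec[j] = (loss(tp) - loss(tm)) / (2.0 * h)
            return gvec

    res = scipy.optimize.minimize(
        loss, theta0, jac=jacfun, method="BFGS",
        options={"maxiter": opts.max_iter, "gtol": opts.tol},
    )
    if not res.success and res.status != 2:
        import warnings

        warnings.warn(f"global optimizer did not converge: {res.message}", RuntimeWarning)
    return np.asarray(res.x, dtype=float)
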