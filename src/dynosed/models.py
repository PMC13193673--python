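"""Drift families, diffusion specifications, and built-in demonstration systems.

All state-dependent callables follow one broadcasting convention: a state
argument may be a single point of shape ``(d,)`` or a batch of shape
``(N, d)``, and the output gains the corresponding leading axis.  Scalars
(divergences) come back as ``float`` for a single point and ``(N,)`` arrays
for batches.  This lets the simulator advance thousands of independent
trajectories with one vectorized drift evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np


class ShapeError(ValueError):
    """Dimension mismatch between a state, parameter vector, or matrix."""


def _as_batch(x: np.ndarray, dim: int) -> tuple[np.ndarray, bool]:
    """Return ``(X, single)`` with X of shape (N, dim); ``single`` marks a 1-D input."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        if x.shape[0] != dim:
            raise ShapeError(f"state has length {x.shape[0]}, expected {dim}")
        return x[None, :], True
    if x.ndim == 2:
        if x.shape[1] != dim:
            raise ShapeError(f"state batch has width {x.shape[1]}, expected {dim}")
        return x, False
    raise ShapeError(f"state must be 1-D or 2-D, got ndim={x.ndim}")


@dataclass
class DiffusionSpec:
    """Diffusion matrix D(x) = G(x) G(x)^T / 2 of an Ito SDE.

    For a constant diffusion only ``constant_D`` is needed.  A state-dependent
    diffusion must also supply its divergence fields: ``divD_of_x`` maps a
    state to the d-vector with component j equal to sum_i dD_ij/dx_i, and
    ``divdivD_of_x`` to the scalar double divergence.  Units of D are
    state^2 / time.
    """

    dim: int
    constant_D: Optional[np.ndarray] = None
    D_of_x: Optional[Callable[[np.ndarray], np.ndarray]] = None
    divD_of_x: Optional[Callable[[np.ndarray], np.ndarray]] = None
    divdivD_of_x: Optional[Callable[[np.ndarray], float]] = None
    is_constant: bool = True

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ShapeError("dim must be a positive integer")
        if self.is_constant:
            if self.constant_D is None:
                raise ValueError("constant diffusion requires constant_D")
            D = np.asarray(self.constant_D, dtype=float)
            if D.shape != (self.dim, self.dim):
                raise ShapeError(f"constant_D has shape {D.shape}, expected {(self.dim,) * 2}")
            _check_symmetric_psd(D)
            self.constant_D = D
        else:
            if self.D_of_x is None:
                raise ValueError("state-dependent diffusion requires D_of_x")
            if self.divD_of_x is None or self.divdivD_of_x is None:
                raise ValueError(
                    "state-dependent diffusion requires divD_of_x and divdivD_of_x"
                )

    def D(self, x: np.ndarray) -> np.ndarray:
        """Evaluate D at a single state (shape (d, d))."""
        if self.is_constant:
            return self.constant_D
        D = np.asarray(self.D_of_x(np.asarray(x, dtype=float)), dtype=float)
        _check_symmetric_psd(D)
        return D

    def sqrt_D(self, x: Optional[np.ndarray] = None) -> np.ndarray:
        """Symmetric PSD square root L with L @ L = D (used by the integrator)."""
        D = self.constant_D if self.is_constant else self.D(x)
        w, V = np.linalg.eigh(D)
        w = np.clip(w, 0.0, None)
        return (V * np.sqrt(w)) @ V.T


def _check_symmetric_psd(D: np.ndarray, tol: float = 1e-10) -> None:
    if not np.allclose(D, D.T, atol=tol):
        raise ValueError("diffusion matrix is not symmetric")
    w = np.linalg.eigvalsh(0.5 * (D + D.T))
    if np.min(w) < -tol:
        raise ValueError(f"diffusion matrix has negative eigenvalue {np.min(w):.3e}")


def constant_diffusion(D: np.ndarray | float, dim: Optional[int] = None) -> DiffusionSpec:
    """Convenience constructor: a scalar means D = scalar * I."""
    if np.isscalar(D):
        if dim is None:
            raise ValueError("dim required when D is a scalar")
        D = float(D) * np.eye(dim)
    D = np.asarray(D, dtype=float)
    return DiffusionSpec(dim=D.shape[0], constant_D=D, is_constant=True)


@dataclass
class ParametricDrift:
    """A drift family f_theta(x) with its analytic state-divergence.

    ``drift(x, theta)`` returns the d-vector field, ``divergence(x, theta)``
    its divergence in x, and the optional ``param_gradient(x, theta)`` the
    (d, n) Jacobian in theta (used by gradient-based fitting).
    """

    dim_state: int
    dim_params: int
    drift: Callable[[np.ndarray, np.ndarray], np.ndarray]
    divergence: Callable[[np.ndarray, np.ndarray], np.ndarray]
    param_gradient: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    name: str = "parametric"


@dataclass
class AffineColumnStructure:
    """Sparse column structure of an affine basis U(x).

    Many drift families have basis columns of the form u_q(x) e_g (a scalar
    basis function times one state unit vector).  ``scalar_basis`` maps a
    state batch to the (N, q) matrix of scalar functions and ``columns``
    lists, per parameter, the pair (state_index g, scalar_index q).  When
    present, the simulator and the global-route assembly use this factored
    form, which is much cheaper than materializing dense (N, d, n) arrays.
    """

    scalar_basis: Callable[[np.ndarray], np.ndarray]
    columns: Sequence[tuple[int, int]]


@dataclass
class AffineDrift:
    """Affine-in-parameter drift f_theta(x) = U(x) theta + v(x).

    ``U(x)`` maps a state to the (d, n) matrix of basis vector fields,
    ``v(x)`` to the known d-vector field.  ``divU(x)`` holds the n state-
    divergences of the columns of U and ``divv(x)`` the divergence of v;
    both are supplied analytically and validated numerically in the tests.
    The class is drop-in usable wherever a :class:`ParametricDrift` is
    expected (it exposes ``drift``/``divergence``/``param_gradient``).
    ``structure`` optionally records a sparse factorization of U used for
    fast simulation and assembly; it must agree with U (tested).
    """

    dim_state: int
    dim_params: int
    U: Callable[[np.ndarray], np.ndarray]
    v: Callable[[np.ndarray], np.ndarray]
    divU: Callable[[np.ndarray], np.ndarray]
    divv: Callable[[np.ndarray], np.ndarray]
    names: Sequence[str] = field(default_factory=list)
    name: str = "affine"
    structure: Optional[AffineColumnStructure] = None

    def __post_init__(self) -> None:
        if not self.names:
            self.names = [f"theta_{j}" for j in range(self.dim_params)]
        if len(self.names) != self.dim_params:
            raise ShapeError("names must have one label per parameter")

    def _theta(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.shape[0] != self.dim_params:
            raise ShapeError(
                f"theta has length {theta.shape[0]}, expected {self.dim_params}"
            )
        return theta

    def drift(self, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        theta = self._theta(theta)
        X, single = _as_batch(x, self.dim_state)
        if self.structure is not None:
            basis = np.asarray(self.structure.scalar_basis(X), dtype=float)
            C = np.zeros((basis.shape[1], self.dim_state))
            for k, (g, q) in enumerate(self.structure.columns):
                C[q, g] += theta[k]
            out = basis @ C
        else:
            out = np.einsum("ndk,k->nd", np.asarray(self.U(X), dtype=float), theta)
        out = out + np.asarray(self.v(X), dtype=float)
        return out[0] if single else out

    def divergence(self, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        theta = self._theta(theta)
        X, single = _as_batch(x, self.dim_state)
        out = np.asarray(self.divU(X), dtype=float) @ theta
        out = out + np.asarray(self.divv(X), dtype=float)
        return float(out[0]) if single else out

    def param_gradient(self, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        X, single = _as_batch(x, self.dim_state)
        out = np.asarray(self.U(X), dtype=float)
        return out[0] if single else out


def affine_eval(aff: AffineDrift, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate f_theta(x) = U(x) theta + v(x)."""
    return aff.drift(x, theta)


def affine_divergence(aff: AffineDrift, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate div_x f_theta(x) = divU(x) . theta + divv(x)."""
    return aff.divergence(x, theta)


# ---------------------------------------------------------------------------
# Built-in systems
# ---------------------------------------------------------------------------


def ou_affine(
    param_mats: Optional[Sequence[np.ndarray]] = None,
    fixed_mat: Optional[np.ndarray] = None,
) -> AffineDrift:
    """Linear (Ornstein-Uhlenbeck) drift in an affine prior family.

    The family is M(theta) x with M(theta) = sum_j theta_j P_j + M0: the
    columns of U(x) are P_j x, v(x) = M0 x, divU_j = trace(P_j), and
    divv = trace(M0).  The default single-parameter family is
    M(theta) = [[theta, 1], [-1, theta]]: a shared decay rate theta plus a
    fixed rotation, whose rotational probability current makes the drift
    unidentifiable from the stationary density without the prior.
    """
    if param_mats is None:
        param_mats = [np.eye(2)]
    if fixed_mat is None:
        fixed_mat = np.array([[0.0, 1.0], [-1.0, 0.0]])
    P = [np.asarray(m, dtype=float) for m in param_mats]
    M0 = np.asarray(fixed_mat, dtype=float)
    if M0.ndim != 2 or M0.shape[0] != M0.shape[1]:
        raise ShapeError("fixed part must be a square matrix")
    d = M0.shape[0]
    for m in P:
        if m.shape != (d, d):
            raise ShapeError(f"parameter matrix has shape {m.shape}, expected {(d, d)}")
    n = len(P)
    Pstack = np.stack(P)  # (n, d, d)
    traces = np.array([np.trace(m) for m in P])
    tr0 = float(np.trace(M0))

    def U(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, d)
        return np.einsum("kde,ne->ndk", Pstack, X)

    def v(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, d)
        return X @ M0.T

    def divU(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, d)
        return np.broadcast_to(traces, (X.shape[0], n)).copy()

    def divv(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, d)
        return np.full(X.shape[0], tr0)

    return AffineDrift(
        dim_state=d, dim_params=n, U=U, v=v, divU=divU, divv=divv,
        names=[f"theta_{j}" for j in range(n)], name="ou",
    )


def lorenz_affine() -> AffineDrift:
    """The Lorenz drift with theta = (sigma, rho, beta) as free parameters.

    f(x, y, z) = (sigma (y - x), x (rho - z) - y, x y - beta z), split as
    U(x) = [[y-x, 0, 0], [0, x, 0], [0, 0, -z]], v(x) = (0, -y - x z, x y).
    """

    def U(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, 3)
        N = X.shape[0]
        out = np.zeros((N, 3, 3))
        out[:, 0, 0] = X[:, 1] - X[:, 0]
        out[:, 1, 1] = X[:, 0]
        out[:, 2, 2] = -X[:, 2]
        return out

    def v(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, 3)
        out = np.zeros_like(X)
        out[:, 1] = -X[:, 1] - X[:, 0] * X[:, 2]
        out[:, 2] = X[:, 0] * X[:, 1]
        return out

    def divU(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, 3)
        return np.broadcast_to(np.array([-1.0, 0.0, -1.0]), (X.shape[0], 3)).copy()

    def divv(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, 3)
        return np.full(X.shape[0], -1.0)

    def scalar_basis(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, 3)
        return np.stack([X[:, 1] - X[:, 0], X[:, 0], -X[:, 2]], axis=-1)

    structure = AffineColumnStructure(scalar_basis, [(0, 0), (1, 1), (2, 2)])
    return AffineDrift(
        dim_state=3, dim_params=3, U=U, v=v, divU=divU, divv=divv,
        names=["sigma", "rho", "beta"], name="lorenz", structure=structure,
    )


def lorenz_true_params() -> np.ndarray:
    """Classical chaotic parameter values used as the fixture ground truth."""
    return np.array([10.0, 28.0, 8.0 / 3.0])


# --- gene-regulatory network -----------------------------------------------

GRN_INPUT_NAMES = ("pi", "beta", "rho", "pi*beta", "pi*rho", "beta*rho", "pi*beta*rho")
GRN_STATE_NAMES = ("p", "b", "r", "o1", "o2", "o3", "o4")


@dataclass
class GRNConfig:
    """Configuration of the seven-dimensional gene-regulatory demonstration.

    Three gene activities (p, b, r) are regulated through third-order
    interactions of the sigmoid-transformed activities pi = 1/(1+p^2),
    beta = 1/(1+b^2), rho = 1/(1+r^2) via a 3x7 interaction matrix W (the
    unknown).  The known drift part carries linear degradation of the genes,
    additive drive from two autonomous Stuart-Landau (Hopf normal-form)
    oscillators standing in for the BCR/CD40 pathways, and the oscillator
    dynamics themselves.
    """

    degradation: tuple[float, float, float] = (1.0, 1.0, 0.8)
    # additive pathway drives: osc1 -> p (first coordinate), osc2 -> b (first
    # coordinate), and optionally osc1's second coordinate -> r (off by
    # default: the r gene is excited by its intrinsic noise alone, which
    # keeps rho the least-varying activity and preserves the triple-product
    # near-redundancy)
    drive_gains: tuple[float, float, float] = (1.5, 1.5, 0.0)
    osc_radius: float = 1.0
    osc_freqs: tuple[float, float] = (1.0, 1.3)
    osc_relax: float = 1.0


def grn_regulatory_inputs(X: np.ndarray) -> np.ndarray:
    """The 7-vector u(x) = (pi, beta, rho, pi*beta, pi*rho, beta*rho, pi*beta*rho)."""
    X, single = _as_batch(X, 7)
    pi = 1.0 / (1.0 + X[:, 0] ** 2)
    be = 1.0 / (1.0 + X[:, 1] ** 2)
    rh = 1.0 / (1.0 + X[:, 2] ** 2)
    u = np.stack([pi, be, rh, pi * be, pi * rh, be * rh, pi * be * rh], axis=-1)
    return u[0] if single else u


def _grn_input_gene_derivs(X: np.ndarray) -> np.ndarray:
    """d u_j / d x_g for the three gene coordinates: shape (N, 3, 7)."""
    p, b, r = X[:, 0], X[:, 1], X[:, 2]
    pi = 1.0 / (1.0 + p**2)
    be = 1.0 / (1.0 + b**2)
    rh = 1.0 / (1.0 + r**2)
    dpi = -2.0 * p * pi**2
    dbe = -2.0 * b * be**2
    drh = -2.0 * r * rh**2
    N = X.shape[0]
    out = np.zeros((N, 3, 7))
    # derivative w.r.t. p hits every factor pi
    out[:, 0, 0] = dpi
    out[:, 0, 3] = dpi * be
    out[:, 0, 4] = dpi * rh
    out[:, 0, 6] = dpi * be * rh
    # w.r.t. b
    out[:, 1, 1] = dbe
    out[:, 1, 3] = pi * dbe
    out[:, 1, 5] = dbe * rh
    out[:, 1, 6] = pi * dbe * rh
    # w.r.t. r
    out[:, 2, 2] = drh
    out[:, 2, 4] = pi * drh
    out[:, 2, 5] = be * drh
    out[:, 2, 6] = pi * be * drh
    return out


def grn_affine(config: Optional[GRNConfig] = None) -> AffineDrift:
    """Seven-dimensional gene-regulatory drift, affine in the 21 entries of W.

    theta is the row-major flattening of the 3x7 interaction matrix W: the
    gene-g drift receives W[g, :] . u(x).  The four oscillator coordinates
    carry no free parameters.
    """
    cfg = config or GRNConfig()
    gam = np.asarray(cfg.degradation, dtype=float)
    a1, a2, a3 = cfg.drive_gains
    mu2 = cfg.osc_radius**2
    w1, w2 = cfg.osc_freqs
    kap = cfg.osc_relax

    def U(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, 7)
        u = grn_regulatory_inputs(X)
        N = X.shape[0]
        out = np.zeros((N, 7, 21))
        for g in range(3):
            out[:, g, 7 * g : 7 * (g + 1)] = u
        return out

    def v(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, 7)
        out = np.zeros_like(X)
        out[:, :3] = -X[:, :3] * gam
        out[:, 0] += a1 * X[:, 3]
        out[:, 1] += a2 * X[:, 5]
        out[:, 2] += a3 * X[:, 4]
        r1 = X[:, 3] ** 2 + X[:, 4] ** 2
        r2 = X[:, 5] ** 2 + X[:, 6] ** 2
        out[:, 3] = kap * (mu2 - r1) * X[:, 3] - w1 * X[:, 4]
        out[:, 4] = kap * (mu2 - r1) * X[:, 4] + w1 * X[:, 3]
        out[:, 5] = kap * (mu2 - r2) * X[:, 5] - w2 * X[:, 6]
        out[:, 6] = kap * (mu2 - r2) * X[:, 6] + w2 * X[:, 5]
        return out

    def divU(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, 7)
        d = _grn_input_gene_derivs(X)  # (N, 3, 7)
        return d.reshape(X.shape[0], 21)

    def divv(X: np.ndarray) -> np.ndarray:
        X, _ = _as_batch(X, 7)
        r1 = X[:, 3] ** 2 + X[:, 4] ** 2
        r2 = X[:, 5] ** 2 + X[:, 6] ** 2
        osc = kap * (2.0 * mu2 - 4.0 * r1) + kap * (2.0 * mu2 - 4.0 * r2)
        return -gam.sum() + osc

    names = [f"W[{g},{j}]" for g in range(3) for j in range(7)]
    structure = AffineColumnStructure(
        grn_regulatory_inputs, [(g, j) for g in range(3) for j in range(7)]
    )
    return AffineDrift(
        dim_state=7, dim_params=21, U=U, v=v, divU=divU, divv=divv,
        names=names, name="grn", structure=structure,
    )


def grn_true_matrix() -> np.ndarray:
    """Fixture ground-truth 3x7 interaction matrix (package convention).

    Sparse, with both activation and repression.  The third-order input
    pi*beta*rho is nearly expressible as a combination of the lower-order
    inputs over the explored activity range, so the columns involving it
    form near-redundant directions -- the over-parameterization the freeness
    diagnostic is meant to expose.
    """
    return np.array(
        [
            [1.5, 0.0, 0.0, -1.0, 0.0, 0.0, 0.8],
            [0.9, 1.2, -0.6, 0.0, 0.0, 0.0, -0.9],
            [1.0, 0.0, 0.0, 0.0, 0.0, -0.5, 0.0],
        ]
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


@dataclass
class ModelEntry:
    """A named demonstration system: drift family, fixture truth, defaults."""

    name: str
    build: Callable[[], AffineDrift]
    true_theta: np.ndarray
    default_diffusion: Callable[[], DiffusionSpec]
    default_dt: float
    default_x0: np.ndarray
    state_names: tuple[str, ...]


def _registry() -> dict[str, ModelEntry]:
    return {
        "ou": ModelEntry(
            name="ou",
            build=ou_affine,
            true_theta=np.array([-2.0]),
            default_diffusion=lambda: constant_diffusion(1.0, dim=2),
            default_dt=1e-2,
            default_x0=np.zeros(2),
            state_names=("x1", "x2"),
        ),
        "lorenz": ModelEntry(
            name="lorenz",
            build=lorenz_affine,
            true_theta=lorenz_true_params(),
            default_diffusion=lambda: constant_diffusion(1.0, dim=3),
            default_dt=1e-3,
            default_x0=np.array([1.0, 1.0, 20.0]),
            state_names=("x", "y", "z"),
        ),
        "grn": ModelEntry(
            name="grn",
            build=grn_affine,
            true_theta=grn_true_matrix().ravel(),
            default_diffusion=lambda: constant_diffusion(0.05, dim=7),
            default_dt=1e-3,
            default_x0=np.array([0.8, 0.8, 0.5, 0.0, 0.0, 0.0, 0.0]),
            state_names=GRN_STATE_NAMES,
        ),
    }


MODEL_REGISTRY = _registry()


def get_model(name: str) -> ModelEntry:
    """Look up a built-in demonstration system by name ('ou', 'lorenz', 'grn')."""
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
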