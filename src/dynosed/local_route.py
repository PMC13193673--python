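"""Local score-based identification route.

The stationary Fokker-Planck equation, divided through by the density,
yields a pointwise residual in terms of the score s = grad log p:

    R_local(x; theta) = s^T f_theta + div f_theta - s^T D s - Tr(D grad s),

zero at the true parameters for every x.  With estimated scores at m probe
points the mean squared residual is the local loss; for affine drifts
f_theta = U theta + v the residual is linear in theta and minimization
collapses to a least-squares system A theta = b.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.optimize

from .models import AffineDrift, DiffusionSpec, ParametricDrift
from .score import ScoreField


class DiffusionConfigError(ValueError):
    """State-dependent diffusion used without its divergence fields."""


@dataclass
class LinearSystem:
    """The assembled least-squares system A theta = b of either route."""

    A: np.ndarray
    b: np.ndarray
    route: str = "local"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.asarray(self.b, dtype=float).ravel()
        if self.A.shape[0] != self.b.shape[0]:
            raise ValueError(
                f"A has {self.A.shape[0]} rows but b has {self.b.shape[0]} entries"
            )
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.b))):
            raise ValueError("linear system contains non-finite entries")

    @property
    def n_params(self) -> int:
        return self.A.shape[1]

    def to_csv(self, path: Union[str, Path]) -> None:
        n = self.n_params
        cols = {f"A{j}": self.A[:, j] for j in range(n)}
        cols["b"] = self.b
        df = pd.DataFrame(cols)
        df.attrs["route"] = self.route
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: Union[str, Path], route: str = "local") -> "LinearSystem":
        df = pd.read_csv(path)
        if "b" not in df.columns:
            raise ValueError(f"{path}: malformed linear-system file (no 'b' column)")
        b = df.pop("b").to_numpy()
        return cls(df.to_numpy(dtype=float), b, route=route)


def _residual_terms(
    diffusion: DiffusionSpec, s: np.ndarray, jac_s: np.ndarray, x: np.ndarray
) -> float:
    """The theta-independent diffusion part: s^T D s + Tr(D jac) [+ divD terms]."""
    D = diffusion.D(x)
    out = float(s @ D @ s) + float(np.einsum("ij,ji->", D, jac_s))
    if not diffusion.is_constant:
        if diffusion.divD_of_x is None or diffusion.divdivD_of_x is None:
            raise DiffusionConfigError(
                "state-dependent diffusion requires divD_of_x and divdivD_of_x"
            )
        divD = np.asarray(diffusion.divD_of_x(x), dtype=float)
        out += float(s @ divD) + float(diffusion.divdivD_of_x(x))
    return out


def local_residual(
    drift: ParametricDrift,
    theta: np.ndarray,
    diffusion: DiffusionSpec,
    s: np.ndarray,
    jac_s: np.ndarray,
    x: np.ndarray,
    dtlogp: float = 0.0,
) -> float:
    """Pointwise Fokker-Planck residual in score form at one state.

    Constant D:   s^T f + div f - s^T D s - Tr(D grad s) + dtlogp.
    State-dependent D additionally subtracts s^T (div D) + div(div D).
    ``dtlogp`` is the known time-derivative of log p (zero when stationary);
    it enters with a plus sign so that the residual vanishes at the truth
    for nonstationary snapshots with a known density drift.
    """
    s = np.asarray(s, dtype=float).ravel()
    jac_s = np.asarray(jac_s, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    f = np.asarray(drift.drift(x, theta), dtype=float).ravel()
    divf = float(drift.divergence(x, theta))
    return float(s @ f) + divf - _residual_terms(diffusion, s, jac_s, x) + dtlogp


def local_loss(
    drift: ParametricDrift,
    theta: np.ndarray,
    diffusion: DiffusionSpec,
    field: ScoreField,
) -> float:
    """Mean squared local residual over the probe points (the local loss)."""
    if field.m == 0:
        raise ValueError("score field is empty")
    total = 0.0
    for i in range(field.m):
        r = local_residual(
            drift, theta, diffusion, field.s_hat[i], field.jac[i],
            field.probes[i], float(field.dtlogp[i]),
        )
        total += r * r
    return total / field.m


def assemble_local_system(
    aff: AffineDrift, diffusion: DiffusionSpec, field: ScoreField
) -> LinearSystem:
    """Assemble the local-route system A theta = b from an affine drift.

    Row i is a(x_i)^T = (U(x_i)^T s_i + divU(x_i))^T and

        b_i = s_i^T D s_i + Tr(D jac_i) - s_i^T v(x_i) - divv(x_i) - dtlogp_i

    (state-dependent D adds its divergence corrections to b), so that
    a(x)^T theta - b(x) equals the local residual for every theta.
    """
    if aff.dim_state != field.dim:
        raise ValueError(
            f"model dimension {aff.dim_state} does not match probes of dimension {field.dim}"
        )
    m, n = field.m, aff.dim_params
    A = np.empty((m, n))
    b = np.empty(m)
    Uall = np.asarray(aff.U(field.probes), dtype=float)  # (m, d, n)
    vall = np.asarray(aff.v(field.probes), dtype=float)  # (m, d)
    divU = np.asarray(aff.divU(field.probes), dtype=float)  # (m, n)
    divv = np.asarray(aff.divv(field.probes), dtype=float)  # (m,)
    for i in range(m):
        s = field.s_hat[i]
        A[i] = Uall[i].T @ s + divU[i]
        b[i] = (
            _residual_terms(diffusion, s, field.jac[i], field.probes[i])
            - float(s @ vall[i])
            - float(divv[i])
            - float(field.dtlogp[i])
        )
    meta = {
        "n_probes": m,
        "estimator": field.config.estimator_name,
        "bandwidth": field.config.bandwidth,
        "model": aff.name,
    }
    return LinearSystem(A, b, route="local", meta=meta)


@dataclass
class OptimizerOptions:
    """Deterministic quasi-Newton settings for the non-affine path."""

    tol: float = 1e-12
    max_iter: int = 500
    fd_step: float = 1e-6


def minimize_local(
    drift: ParametricDrift,
    diffusion: DiffusionSpec,
    field: ScoreField,
    theta0: np.ndarray,
    opts: Optional[OptimizerOptions] = None,
) -> np.ndarray:
    """Minimize the local loss by deterministic quasi-Newton (BFGS).

    Gradients use the drift's analytic theta-derivative of the residual when
    the drift is affine; otherwise central finite differences with step
    fd_step * (1 + |theta_j|).  For affine drifts the minimizer agrees with
    the lambda = 0 linear solve of the assembled system (convex quadratic).
    """
    opts = opts or OptimizerOptions()
    theta0 = np.asarray(theta0, dtype=float).ravel()

    def loss(th: np.ndarray) -> float:
        return local_loss(drift, th, diffusion, field)

    jacfun = None
    if isinstance(drift, AffineDrift):
        sys_ = assemble_local_system(drift, diffusion, field)
        A, b = sys_.A, sys_.b

        def loss(th: np.ndarray) -> float:  # noqa: F811 - quadratic fast path
            r = A @ th - b
            return float(r @ r) / A.shape[0]

        def jacfun(th: np.ndarray) -> np.ndarray:
            return 2.0 * A.T @ (A @ th - b) / A.shape[0]

    else:

        def jacfun(th: np.ndarray) -> np.ndarray:
            g = np.empty_like(th)
            for j in range(th.size):
                h = opts.fd_step * (1.0 + abs(th[j]))
                tp, tm = th.copy(), th.copy()
                tp[j] += h
                tm[j] -= h
                g[j] = (loss(tp) - loss(tm)) / (2.0 * h)
            return g

    res = scipy.optimize.minimize(
        loss, theta0, jac=jacfun, method="BFGS",
        options={"maxiter": opts.max_iter, "gtol": opts.tol},
    )
    if not res.success and res.status != 2:  # status 2: precision loss near optimum
        import warnings

        warnings.warn(f"local optimizer did not converge: {res.message}", RuntimeWarning)
    return np.asarray(res.x, dtype=float)
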