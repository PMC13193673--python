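"""Shared fixtures: small analytic systems and finite-difference oracles."""

from __future__ import annotations

import numpy as np
import pytest

import dynosed as dy


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ou_fixture():
    """The one-parameter linear family M(theta) = [[theta, 1], [-1, theta]].

    Ground truth theta = -2; analytic stationary covariance from the
    Lyapunov equation with unit diffusion.
    """
    model = dy.ou_affine()
    theta_true = np.array([-2.0])
    M = np.array([[-2.0, 1.0], [-1.0, -2.0]])
    diffusion = dy.constant_diffusion(1.0, dim=2)
    sigma = dy.ou_stationary_covariance(M, np.eye(2))
    return {
        "model": model,
        "theta_true": theta_true,
        "M": M,
        "diffusion": diffusion,
        "sigma": sigma,
    }


@pytest.fixture(scope="session")
def lorenz_model():
    return dy.lorenz_affine()


@pytest.fixture(scope="session")
def grn_model():
    return dy.grn_affine()


def fd_divergence(drift, x, theta, h=1e-5):
    """Central finite-difference divergence of a drift field (oracle)."""
    x = np.asarray(x, dtype=float)
    total = 0.0
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        total += (drift.drift(xp, theta)[i] - drift.drift(xm, theta)[i]) / (2 * h)
    return total


def fd_jacobian(func, x, h=1e-5):
    """Central finite-difference Jacobian of a vector field R^d -> R^d."""
    x = np.asarray(x, dtype=float)
    d = x.size
    f0 = np.asarray(func(x))
    J = np.empty((f0.size, d))
    for i in range(d):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (np.asarray(func(xp)) - np.asarray(func(xm))) / (2 * h)
    return J


@pytest.fixture()
def random_affine_model(rng):
    """A dense random affine drift in 3 dimensions with polynomial fields."""
    d, n = 3, 4
    A1 = rng.standard_normal((n, d, d))
    a0 = rng.standard_normal((n, d))
    B = rng.standard_normal((d, d))
    b0 = rng.standard_normal(d)

    def U(X):
        X = np.atleast_2d(X)
        # column k: A1[k] x + a0[k]
        return np.einsum("kde,ne->ndk", A1, X) + a0.T[None, :, :]

    def v(X):
        X = np.atleast_2d(X)
        return X @ B.T + b0

    def divU(X):
        X = np.atleast_2d(X)
        tr = np.array([np.trace(A1[k]) for k in range(n)])
        return np.broadcast_to(tr, (X.shape[0], n)).copy()

    def divv(X):
        X = np.atleast_2d(X)
        return np.full(X.shape[0], np.trace(B))

    return dy.AffineDrift(dim_state=d, dim_params=n, U=U, v=v, divU=divU, divv=divv)
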