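"""Steady-state sampling of Ito SDEs and region-restricted sphere selection.

Non-sequential datasets are produced by Euler-Maruyama integration, burn-in,
thinning, and a final row shuffle that destroys all ordering information.
Region-restricted data mimic experiments whose measurements are dense only
inside a few small balls of state space: sphere centers are drawn from the
data cloud itself and double as the probe locations of the local route.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import DiffusionSpec, ParametricDrift, _as_batch


class IntegrationError(RuntimeError):
    """The SDE integrator produced a non-finite state."""


class SphereSelectionError(RuntimeError):
    """No acceptable sphere configuration was found within the attempt budget."""


@dataclass
class SimulationConfig:
    """Settings of one steady-state sampling run.

    ``n_paths`` independent copies of the SDE are advanced in lockstep and
    pooled after burn-in; with the default of 1 the output is a thinned
    single trajectory.  Pooling changes nothing the package consumes, since
    every downstream operation is invariant to row order.
    """

    dt: float
    n_burn: int
    n_keep: int
    thin: int = 1
    x0: Optional[np.ndarray] = None
    seed: int = 0
    n_paths: int = 1
    x0_jitter: Optional[np.ndarray] = None  # per-dim Gaussian spread of initial states

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_burn < 0 or self.n_keep <= 0 or self.thin < 1 or self.n_paths < 1:
            raise ValueError("n_burn >= 0, n_keep > 0, thin >= 1, n_paths >= 1 required")


@dataclass
class RegionConfig:
    """Settings of the sphere-based region restriction."""

    m_spheres: int
    radius: float
    n_min: int
    n_loc: int
    max_attempts: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.m_spheres < 1:
            raise ValueError("radius > 0 and m_spheres >= 1 required")
        if self.n_loc > self.n_min:
            raise ValueError("n_loc must not exceed n_min")


@dataclass
class NonSeqDataset:
    """Unordered state samples: an (N, d) matrix with no temporal semantics.

    ``region_id`` labels rows by the sphere they were sampled from (-1 for
    unrestricted data).  Every consumer of a NonSeqDataset must be invariant
    to row permutation; the test suite enforces this.
    """

    X: np.ndarray
    region_id: Optional[np.ndarray] = None
    names: Sequence[str] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be an (N, d) matrix")
        if not self.names:
            self.names = tuple(f"x{i}" for i in range(self.X.shape[1]))
        if self.region_id is not None:
            self.region_id = np.asarray(self.region_id, dtype=int)
            if self.region_id.shape != (self.X.shape[0],):
                raise ValueError("region_id must have one label per row")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def permuted(self, rng: np.random.Generator) -> "NonSeqDataset":
        """A row-shuffled copy (used by the permutation-invariance tests)."""
        order = rng.permutation(self.n)
        rid = None if self.region_id is None else self.region_id[order]
        return NonSeqDataset(self.X[order], rid, self.names, dict(self.provenance))

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write as delimited text with a header; provenance as a JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.X, columns=list(self.names))
        if self.region_id is not None:
            df["region_id"] = self.region_id
        df.to_csv(path, index=False, float_format="%.12g")
        if self.provenance:
            sidecar = path.with_suffix(path.suffix + ".provenance.json")
            sidecar.write_text(json.dumps(self.provenance, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "NonSeqDataset":
        path = Path(path)
        df = pd.read_csv(path)
        rid = None
        if "region_id" in df.columns:
            rid = df.pop("region_id").to_numpy()
        prov = {}
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        if sidecar.exists():
            prov = json.loads(sidecar.read_text())
        return cls(df.to_numpy(dtype=float), rid, tuple(df.columns), prov)


@dataclass
class ProbeSet:
    """Probe locations for local score estimation: an (m, d) matrix of centers."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))


def _step_batch(
    X: np.ndarray,
    drift: ParametricDrift,
    theta: np.ndarray,
    diffusion: DiffusionSpec,
    dt: float,
    rng: np.random.Generator,
    sqrtD_const: Optional[np.ndarray],
) -> np.ndarray:
    """One Euler-Maruyama step for a batch of states (B, d)."""
    f = np.asarray(drift.drift(X, theta), dtype=float)
    xi = rng.standard_normal(X.shape)
    if sqrtD_const is not None:
        noise = xi @ sqrtD_const.T
    else:
        noise = np.empty_like(X)
        for i in range(X.shape[0]):
            noise[i] = diffusion.sqrt_D(X[i]) @ xi[i]
    return X + f * dt + np.sqrt(2.0 * dt) * noise


def euler_maruyama(
    drift: ParametricDrift,
    theta: np.ndarray,
    diffusion: DiffusionSpec,
    cfg: SimulationConfig,
) -> np.ndarray:
    """Integrate the SDE and return the full trajectory (n_steps + 1, d).

    The scheme is x_{k+1} = x_k + f(x_k; theta) dt + sqrt(2 dt) L xi_k with
    L the symmetric PSD square root of D, so the per-step increment
    covariance is 2 D dt (D = G G^T / 2).  Identical seeds reproduce the
    trajectory bit-for-bit.
    """
    d = drift.dim_state
    x0 = np.zeros(d) if cfg.x0 is None else np.asarray(cfg.x0, dtype=float)
    if x0.shape != (d,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({d},)")
    n_steps = cfg.n_burn + cfg.n_keep * cfg.thin
    rng = np.random.default_rng(cfg.seed)
    sqrtD = diffusion.sqrt_D() if diffusion.is_constant else None
    traj = np.empty((n_steps + 1, d))
    traj[0] = x0
    X = x0[None, :].copy()
    for k in range(n_steps):
        X = _step_batch(X, drift, theta, diffusion, cfg.dt, rng, sqrtD)
        if not np.all(np.isfinite(X)):
            raise IntegrationError(f"non-finite state at step {k + 1}")
        traj[k + 1] = X[0]
    return traj


def draw_steady_samples(
    drift: ParametricDrift,
    theta: np.ndarray,
    diffusion: DiffusionSpec,
    cfg: SimulationConfig,
    names: Sequence[str] = (),
) -> NonSeqDataset:
    """Simulate, discard the burn-in, thin, pool paths, and shuffle rows.

    With ``n_paths > 1`` the burn-in and thinning stride apply to each path;
    after burn-in, the states of all paths are collected every ``thin`` steps
    until ``n_keep`` samples have accumulated.  The final seeded permutation
    removes any residual ordering.
    """
    d = drift.dim_state
    x0 = np.zeros(d) if cfg.x0 is None else np.asarray(cfg.x0, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    sqrtD = diffusion.sqrt_D() if diffusion.is_constant else None
    B = cfg.n_paths
    X = np.broadcast_to(x0, (B, d)).copy()
    if cfg.x0_jitter is not None:
        # overdispersed initialization decorrelates parallel paths (e.g. the
        # phases of autonomous oscillators) long before burn-in alone would
        X = X + rng.standard_normal((B, d)) * np.asarray(cfg.x0_jitter, dtype=float)

    def step(X: np.ndarray, k: int) -> np.ndarray:
        Xn = _step_batch(X, drift, theta, diffusion, cfg.dt, rng, sqrtD)
        if not np.all(np.isfinite(Xn)):
            raise IntegrationError(f"non-finite state at step {k}")
        return Xn

    k = 0
    for _ in range(cfg.n_burn):
        X = step(X, k)
        k += 1
    rounds = -(-cfg.n_keep // B)  # ceil
    kept = np.empty((rounds * B, d))
    for rr in range(rounds):
        for _ in range(cfg.thin):
            X = step(X, k)
            k += 1
        kept[rr * B : (rr + 1) * B] = X
    kept = kept[: cfg.n_keep]
    kept = kept[rng.permutation(cfg.n_keep)]
    prov = {
        "generator": "euler_maruyama",
        "dt": cfg.dt,
        "n_burn": cfg.n_burn,
        "n_keep": cfg.n_keep,
        "thin": cfg.thin,
        "n_paths": cfg.n_paths,
        "seed": cfg.seed,
        "x0": list(map(float, x0)),
        "theta": list(map(float, np.atleast_1d(theta))),
        "model": getattr(drift, "name", "unknown"),
    }
    return NonSeqDataset(kept, None, names, prov)


def select_spheres(
    data: NonSeqDataset, cfg: RegionConfig
) -> tuple[ProbeSet, NonSeqDataset]:
    """Rejection-sample non-overlapping dense spheres and subsample them.

    Repeatedly draws ``m_spheres`` distinct candidate centers uniformly from
    the data rows and accepts the set iff all pairwise center distances
    exceed 2r (disjoint closed balls) and every ball of radius r holds at
    least ``n_min`` rows.  On acceptance, exactly ``n_loc`` rows are drawn
    uniformly without replacement from each ball; ``region_id`` records the
    ball index.
    """
    if data.n < cfg.n_min:
        raise SphereSelectionError(
            f"dataset has {data.n} rows, fewer than n_min={cfg.n_min}"
        )
    rng = np.random.default_rng(cfg.seed)
    X = data.X
    best_deficit = np.inf
    for attempt in range(cfg.max_attempts):
        idx = rng.choice(data.n, size=cfg.m_spheres, replace=False)
        centers = X[idx]
        if cfg.m_spheres > 1:
            diff = centers[:, None, :] - centers[None, :, :]
            dist = np.sqrt((diff**2).sum(-1))
            iu = np.triu_indices(cfg.m_spheres, 1)
            if np.min(dist[iu]) <= 2.0 * cfg.radius:
                continue
        members = []
        counts = np.empty(cfg.m_spheres, dtype=int)
        for j in range(cfg.m_spheres):
            d2 = ((X - centers[j]) ** 2).sum(-1)
            inside = np.flatnonzero(d2 <= cfg.radius**2)
            members.append(inside)
            counts[j] = inside.size
        deficit = max(0, cfg.n_min - int(counts.min()))
        best_deficit = min(best_deficit, deficit)
        if deficit > 0:
            continue
        rows, labels = [], []
        for j in range(cfg.m_spheres):
            take = rng.choice(members[j], size=cfg.n_loc, replace=False)
            rows.append(X[take])
            labels.append(np.full(cfg.n_loc, j))
        Xr = np.concatenate(rows)
        rid = np.concatenate(labels)
        order = rng.permutation(Xr.shape[0])
        prov = dict(data.provenance)
        prov.update(
            {
                "region_selection": "spheres",
                "m_spheres": cfg.m_spheres,
                "radius": cfg.radius,
                "n_min": cfg.n_min,
                "n_loc": cfg.n_loc,
                "region_seed": cfg.seed,
                "attempts_used": attempt + 1,
            }
        )
        restricted = NonSeqDataset(Xr[order], rid[order], data.names, prov)
        return ProbeSet(centers), restricted
    detail = (
        "all candidate sets violated the pairwise distance > 2r constraint"
        if not np.isfinite(best_deficit)
        else f"best attempt was short {int(best_deficit)} samples of n_min={cfg.n_min}"
    )
    raise SphereSelectionError(
        f"no acceptable sphere set in {cfg.max_attempts} attempts; {detail}"
    )
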