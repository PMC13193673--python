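"""Worked linear example: why a prior family is needed, and how it restores
identifiability.

A 2-D Ornstein-Uhlenbeck process dx = M x dt + sqrt(2) dw has a Gaussian
stationary law that many different drifts share (any divergence-free
probability current can be added).  Restricting M to the one-parameter
family M(theta) = [[theta, 1], [-1, theta]] makes theta identifiable: the
local Fokker-Planck route with exact stationary scores recovers it from a
single linear solve.
"""

import numpy as np

import dynosed as dy

theta_true = -2.0
model = dy.ou_affine()  # the family above: U(x) = x, v(x) = (x2, -x1)
diffusion = dy.constant_diffusion(1.0, dim=2)

M = theta_true * np.eye(2) + np.array([[0.0, 1.0], [-1.0, 0.0]])
sigma = dy.ou_stationary_covariance(M, np.eye(2))
print(f"stationary covariance (Lyapunov solve):\n{sigma}")

rng = np.random.default_rng(0)
probes = rng.multivariate_normal(np.zeros(2), sigma, size=20)
score_cfg = dy.ScoreEstimatorConfig(
    estimator_name="analytic_gaussian", mean=np.zeros(2), cov=sigma
)
report = dy.fit_local(
    dy.NonSeqDataset(probes), model, diffusion, score_cfg,
    probes=dy.ProbeSet(probes),
)

print(f"recovered theta  = {report.theta_hat[0]:+.12f}   (truth {theta_true:+.1f})")
print(f"system rank      = {report.ident.rank}  (unique: {report.ident.unique})")
print(f"residual norm    = {report.solve.residual_norm:.2e}")
# With exact scores the linear system is exactly consistent, so the recovered
# parameter matches the truth to machine precision and the residual is ~1e-16.
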