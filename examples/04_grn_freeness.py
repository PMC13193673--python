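"""Over-parameterized gene-network inference with sensitivity analysis.

Three genes (p, b, r) regulated through third-order interactions of the
transformed activities pi = 1/(1+p^2), beta, rho, driven by two autonomous
oscillators: a 7-D SDE whose 3x7 interaction matrix W is inferred from
unordered steady-state samples by the global kernel-Stein route.  The
"freeness" diagnostic -- the diagonal of (A'A + lambda I)^{-1} -- flags
which entries the data genuinely constrain.

Desk-scale run (~40 s).
"""

import numpy as np

import dynosed as dy

entry = dy.get_model("grn")
model, diffusion = entry.build(), entry.default_diffusion()
W_true = entry.true_theta.reshape(3, 7)

cfg = dy.SimulationConfig(
    dt=1e-3, n_burn=10_000, n_keep=200_000, thin=150,
    x0=entry.default_x0, seed=0, n_paths=1000,
    x0_jitter=np.array([0.3, 0.3, 0.3, 1.0, 1.0, 1.0, 1.0]),
)
data = dy.draw_steady_samples(model, entry.true_theta, diffusion, cfg)

# coordinates of the same physical kind share an RBF lengthscale
sd = data.X.std(axis=0)
ell = np.concatenate([np.full(3, 1.5 * sd[:3].mean()), np.full(4, 2.0 * sd[3:].mean())])
report = dy.fit_global(
    data, model, diffusion, n_features=2000, lengthscale=ell,
    basis_seed=1000, lam=1e-6, single_precision=True,
)
W_hat = report.theta_hat.reshape(3, 7)
free = report.solve.freeness_norm.reshape(3, 7)

np.set_printoptions(precision=2, suppress=True)
print("true W (rows p,b,r; columns pi,beta,rho,pi*beta,pi*rho,beta*rho,pi*beta*rho):")
print(W_true)
print("inferred W:")
print(W_hat)
print("normalized freeness (1 = least constrained):")
print(free)
worst = np.unravel_index(np.argmax(np.abs(W_hat - W_true)), (3, 7))
print(f"largest error at W[{worst[0]},{worst[1]}], "
      f"freeness rank {int(np.sum(free > free[worst]))} of 21")
# The product columns are nearly redundant with lower-order inputs over the
# explored activity range: estimation errors concentrate in that
# high-freeness family (here the pi*beta / pi*beta*rho entries), while
# well-constrained entries are recovered to a few percent.
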