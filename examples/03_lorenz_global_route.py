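"""Sparse global identification of the stochastic Lorenz system.

Only 300 unordered steady-state samples, spread over the whole attractor:
too few for any density or score estimate.  The global route instead drives
the kernel Stein discrepancy to zero -- with random Fourier features the
loss is linear in the sample count, and for the affine-in-parameter Lorenz
drift it collapses to a 2000 x 3 least-squares system.
"""

import numpy as np

import dynosed as dy

entry = dy.get_model("lorenz")
model, diffusion = entry.build(), entry.default_diffusion()
truth = entry.true_theta

for n in (300, 1000, 3000):
    cfg = dy.SimulationConfig(
        dt=1e-3, n_burn=20_000, n_keep=n, thin=50,
        x0=entry.default_x0, seed=0, n_paths=100,
    )
    data = dy.draw_steady_samples(model, truth, diffusion, cfg)
    report = dy.fit_global(
        data, model, diffusion, n_features=2000, lengthscale="median",
        basis_seed=1, lam=0.0,
    )
    rel = 100 * np.abs(report.theta_hat - truth) / truth
    print(f"N = {n:5d}:  (sigma, rho, beta) = "
          + ", ".join(f"{v:7.3f}" for v in report.theta_hat)
          + f"   rel. err. % = " + ", ".join(f"{e:.2f}" for e in rel))
# Error shrinks roughly like 1/sqrt(N); even N = 300 is typically within 10%.
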