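"""Region-restricted identification of the stochastic Lorenz system.

Measurements are confined to ten small spheres on the attractor (the
regime where only local density structure is knowable).  Scores at the
sphere centers are estimated from the in-sphere samples alone with the
boundary-windowed Stein kernel estimator, and the three drift parameters
(sigma, rho, beta) come from the local Fokker-Planck residual least squares.

Desk-scale run (~1 minute): a 6e5-sample cloud and 5e3 points per sphere.
"""

import numpy as np

import dynosed as dy

entry = dy.get_model("lorenz")
model, diffusion = entry.build(), entry.default_diffusion()
truth = entry.true_theta

cfg = dy.SimulationConfig(
    dt=1e-3, n_burn=20_000, n_keep=600_000, thin=5,
    x0=entry.default_x0, seed=0, n_paths=2000,
)
data = dy.draw_steady_samples(model, truth, diffusion, cfg)
print(f"steady-state cloud: {data.n} unordered samples in {data.dim}-D")

region = dy.RegionConfig(m_spheres=10, radius=4.0, n_min=5000, n_loc=5000, seed=1)
score_cfg = dy.ScoreEstimatorConfig(
    bandwidth=49.0, estimator_name="stein_kernel", n_inducing=300, ridge=1e-9
)
report = dy.fit_local(data, model, diffusion, score_cfg, region=region)

for name, th, tr in zip(report.names, report.theta_hat, truth):
    print(f"{name:>6s}: recovered {th:8.3f}   truth {tr:8.3f}   "
          f"({100 * abs(th - tr) / tr:.1f}% off)")
# The kernel bandwidth T = 49 is far wider than any density feature, which
# the Stein-identity estimator tolerates.  At this reduced per-sphere sample
# size the well-excited parameters land within a few percent; beta, the
# least constrained of the three, can be 10-15% off (it tightens with more
# samples per sphere).
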