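# dynosed

**Identifying stochastic dynamics from non-sequential steady-state data.**

Many systems — gene circuits profiled by destructive single-cell assays,
molecules in equilibrium ensembles, ecologies observed in snapshots — are
measured only as *unordered* draws from their stationary distribution: no
time stamps, no trajectories.  Classical system identification does not
apply.  `dynosed` infers the unknown drift parameters θ of an Itô SDE

$$\mathrm{d}x = f_\theta(x)\,\mathrm{d}t + G(x)\,\mathrm{d}w_t,
\qquad D = \tfrac12 G G^\top \text{ known},$$

from such data by minimizing **Fokker–Planck residuals**
$R(x;\theta)=\nabla\!\cdot\!\left(f_\theta p - D\nabla p\right)$, which
vanish identically at the true parameters.  Two complementary routes:

* **Local (score-based)** — for data dense only in a few regions of state
  space.  The residual in score form,
  $R_{\mathrm{loc}} = s^\top f_\theta + \nabla\!\cdot\!f_\theta
  - s^\top D s - \mathrm{Tr}(D\,\nabla s)$ with $s=\nabla\log p$, is
  evaluated at probe points using locally estimated scores (a
  boundary-windowed Stein-identity kernel estimator, or a plain KDE
  gradient).
* **Global (kernel Stein discrepancy)** — for sparse clouds covering the
  whole space.  The residual is enforced weakly over an RBF RKHS; random
  Fourier features make the loss $\|\frac1N\sum_i g(x_i;\theta)\|^2$
  linear in $N$, with an exact $O(N^2)$ KSD kept as an oracle.

For drifts **affine in the parameters**, $f_\theta(x)=U(x)\theta+v(x)$,
both routes reduce to a linear system $A\theta=b$: a consistent θ exists
iff $b\in\mathrm{range}(A)$ and is unique iff $\mathrm{rank}(A)=n$.  The
ridge solution $(A^\top A+\lambda I)^{-1}A^\top b$ comes with a
**freeness** diagnostic — the diagonal of $(A^\top A+\lambda I)^{-1}$ —
that tells you which parameters the data actually constrain.

Built-in demonstration systems: a 2-D Ornstein–Uhlenbeck example (why a
prior family is needed), the stochastic Lorenz attractor, and a 7-D
gene-regulatory network with a 3×7 third-order interaction matrix driven by
two autonomous oscillators.

## Worked example

The drift $Mx$ of a linear SDE cannot be identified from its stationary
density alone — adding any divergence-free probability current leaves $p$
unchanged.  Restricting $M$ to the family
$M(\theta)=\begin{pmatrix}\theta&1\\-1&\theta\end{pmatrix}$ restores
identifiability:

```python
import numpy as np, dynosed as dy

model = dy.ou_affine()                       # U(x) = x, v(x) = (x2, -x1)
diffusion = dy.constant_diffusion(1.0, dim=2)
M = -2.0 * np.eye(2) + np.array([[0., 1.], [-1., 0.]])
sigma = dy.ou_stationary_covariance(M, np.eye(2))   # Lyapunov solve -> I/2

probes = np.random.default_rng(0).multivariate_normal(np.zeros(2), sigma, 20)
cfg = dy.ScoreEstimatorConfig(estimator_name="analytic_gaussian",
                              mean=np.zeros(2), cov=sigma)
report = dy.fit_local(dy.NonSeqDataset(probes), model, diffusion, cfg,
                      probes=dy.ProbeSet(probes))
print(report.theta_hat, report.ident.unique, report.solve.residual_norm)
```

prints

```
[-2.] True 3.925231146709438e-17
```

With exact stationary scores the assembled one-parameter system is exactly
consistent: the decay rate θ = −2 is recovered to machine precision, the
rank condition certifies uniqueness, and the residual is at round-off.
The scripts in `examples/` walk through the other capabilities — the
region-restricted Lorenz fit, the sparse-cloud global fit, and the
gene-network freeness analysis — each printing the recovered parameters
next to the fixture truth.

A thin CLI wraps the same pipelines:

```bash
dynosed simulate --model lorenz --n-keep 3000 --n-paths 100 --thin 50 \
    --seed 7 --out lorenz.csv
dynosed fit --data lorenz.csv --model lorenz --route global --lam 0 --out report.txt
dynosed diagnose --system system.csv --lam 1e-6
```

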