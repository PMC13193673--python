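"""Global route: RFF basis, Stein features, KSD loss, exact oracle, assembly."""

import numpy as np
import pytest

import dynosed as dy
from dynosed.global_route import OracleSizeError


def _ou_data(n, seed=0, theta=-2.0):
    model = dy.ou_affine()
    cfg = dy.SimulationConfig(
        dt=1e-2, n_burn=300, n_keep=n, thin=3, x0=np.zeros(2), seed=seed,
        n_paths=min(50, n),
    )
    return model, dy.draw_steady_samples(
        model, [theta], dy.constant_diffusion(1.0, dim=2), cfg
    )


class TestSampleRFF:
    def test_seed_reproducibility(self):
        b1 = dy.sample_rff(100, 3, 1.5, seed=9)
        b2 = dy.sample_rff(100, 3, 1.5, seed=9)
        assert np.array_equal(b1.omega, b2.omega)
        assert np.array_equal(b1.c, b2.c)
        assert np.all((b1.c >= 0) & (b1.c < 2 * np.pi))

    def test_feature_norm_approximates_kernel_diagonal(self, rng):
        m = 10_000
        basis = dy.sample_rff(m, 2, 1.0, seed=1)
        x = rng.standard_normal(2)
        z = basis.features(x)[0]
        assert abs(z @ z - 1.0) < 4.0 / np.sqrt(m)

    def test_feature_product_converges_to_rbf(self, rng):
        m = 100_000
        ell = 1.3
        basis = dy.sample_rff(m, 2, ell, seed=2)
        for _ in range(5):
            x, y = rng.standard_normal(2), rng.standard_normal(2)
            zx, zy = basis.features(x)[0], basis.features(y)[0]
            k = np.exp(-np.sum((x - y) ** 2) / (2 * ell**2))
            assert abs(zx @ zy - k) < 0.01

    def test_anisotropic_frequencies_scale_per_dimension(self):
        ell = np.array([0.1, 10.0])
        basis = dy.sample_rff(50_000, 2, ell, seed=3)
        sd = basis.omega.std(0)
        assert np.allclose(sd, 1.0 / ell, rtol=0.05)

    def test_multiscale_basis_mixes_lengthscales(self):
        basis = dy.sample_rff_multiscale(3000, 2, [0.5, 2.0, 8.0], seed=4)
        assert basis.m == 3000
        sds = [basis.omega[i * 1000 : (i + 1) * 1000].std() for i in range(3)]
        assert sds[0] > sds[1] > sds[2]


class TestSteinFeature:
    def test_zero_drift_zero_diffusion(self, ou_fixture):
        basis = dy.sample_rff(64, 2, 1.0, seed=0)
        model = dy.ou_affine(param_mats=[np.zeros((2, 2))], fixed_mat=np.zeros((2, 2)))
        g = dy.stein_feature(
            np.ones(2), [0.0], basis, model, dy.constant_diffusion(0.0, dim=2)
        )
        assert np.allclose(g, 0.0)

    def test_single_feature_hand_value(self):
        # omega = e1, c = 0, x = 0: g = -sqrt(2) * D[0,0]
        basis = dy.RFFBasis(
            m=1, omega=np.array([[1.0, 0.0]]), c=np.array([0.0]), lengthscale=1.0
        )
        D = dy.constant_diffusion(np.diag([0.7, 0.3]))
        model = dy.ou_affine()
        g = dy.stein_feature(np.zeros(2), [0.0], basis, model, D)
        assert np.isclose(g[0], -np.sqrt(2.0) * 0.7)

    def test_matches_operator_on_cosine_features(self, ou_fixture, rng):
        """g_r equals f.grad z_r + Tr(D hess z_r), checked by finite differences."""
        model, D = ou_fixture["model"], ou_fixture["diffusion"]
        basis = dy.sample_rff(20, 2, 1.0, seed=5)
        theta = np.array([-2.0])
        x = rng.standard_normal(2)
        f = model.drift(x, theta)
        h = 1e-4
        g_fd = np.empty(20)
        for r in range(20):
            def z(pt, r=r):
                return basis.features(pt)[0, r]

            grad = np.array([
                (z(x + h * e) - z(x - h * e)) / (2 * h) for e in np.eye(2)
            ])
            hess_diag = [
                (z(x + h * e) - 2 * z(x) + z(x - h * e)) / h**2 for e in np.eye(2)
            ]
            e0, e1 = np.eye(2)
            cross = (
                z(x + h * e0 + h * e1) - z(x + h * e0 - h * e1)
                - z(x - h * e0 + h * e1) + z(x - h * e0 - h * e1)
            ) / (4 * h**2)
            H = np.array([[hess_diag[0], cross], [cross, hess_diag[1]]])
            g_fd[r] = f @ grad + np.trace(D.constant_D @ H)
        g = dy.stein_feature(x, theta, basis, model, D)
        assert np.allclose(g, g_fd, atol=1e-5)


class TestGlobalLoss:
    def test_single_zero_sample(self):
        model = dy.ou_affine(param_mats=[np.zeros((2, 2))], fixed_mat=np.zeros((2, 2)))
        basis = dy.sample_rff(32, 2, 1.0, seed=0)
        loss = dy.global_loss(
            np.zeros((1, 2)), [0.0], basis, model, dy.constant_diffusion(0.0, dim=2)
        )
        assert loss == 0.0

    def test_permutation_invariance(self, rng):
        model, data = _ou_data(400, seed=1)
        basis = dy.sample_rff(128, 2, 1.0, seed=1)
        D = dy.constant_diffusion(1.0, dim=2)
        l1 = dy.global_loss(data, [-2.0], basis, model, D)
        l2 = dy.global_loss(data.permuted(rng), [-2.0], basis, model, D)
        assert np.isclose(l1, l2, rtol=1e-12)

    def test_loss_at_truth_decreases_with_n(self):
        """Diffusion-Stein identity: E[g] = 0 at the truth, so the empirical
        loss shrinks with sample size (median over seeds)."""
        D = dy.constant_diffusion(1.0, dim=2)
        med = []
        for n in (100, 1000, 10_000):
            losses = []
            for seed in range(5):
                model, data = _ou_data(n, seed=seed)
                basis = dy.sample_rff(256, 2, 1.5, seed=seed + 100)
                losses.append(dy.global_loss(data, [-2.0], basis, model, D))
            med.append(np.median(losses))
        assert med[0] > med[1] > med[2]

    def test_mean_feature_slope_near_minus_half(self):
        """log-log slope of ||mean Stein feature|| vs N is about -1/2."""
        D = dy.constant_diffusion(1.0, dim=2)
        ns = np.array([100, 1000, 10_000])
        med = []
        for n in ns:
            norms = []
            for seed in range(5):
                model, data = _ou_data(int(n), seed=seed + 20)
                basis = dy.sample_rff(256, 2, 1.5, seed=seed + 300)
                g = dy.mean_stein_feature(data, [-2.0], basis, model, D)
                norms.append(np.linalg.norm(g))
            med.append(np.median(norms))
        slope = np.polyfit(np.log(ns), np.log(med), 1)[0]
        assert abs(slope + 0.5) < 0.15


def nested_fd_double_stein(X, theta, ell, model, Dm, h=1e-2):
    """Finite-difference oracle for (1/N^2) sum_ij A_x A_y k(x_i, x_j).

    Applies the diffusion-Stein operator in y and then in x to the RBF
    kernel using 4th-order central-difference stencils (the value involves
    mixed fourth derivatives of k, so 2nd-order stencils are not accurate
    enough for a 1e-4 comparison)."""
    d = X.shape[1]

    def d1(f, x, i):
        e = np.zeros(d)
        e[i] = h
        return (f(x - 2 * e) - 8 * f(x - e) + 8 * f(x + e) - f(x + 2 * e)) / (12 * h)

    def d2(f, x, i):
        e = np.zeros(d)
        e[i] = h
        return (
            -f(x - 2 * e) + 16 * f(x - e) - 30 * f(x) + 16 * f(x + e) - f(x + 2 * e)
        ) / (12 * h * h)

    def stein(func, x):
        f = model.drift(x, theta)
        grad = np.array([d1(func, x, i) for i in range(d)])
        H = np.empty((d, d))
        for i in range(d):
            H[i, i] = d2(func, x, i)
            for j in range(i + 1, d):
                H[i, j] = H[j, i] = d1(lambda z: d1(func, z, j), x, i)
        return f @ grad + np.trace(Dm @ H)

    def k_sec(x):
        return lambda y: np.exp(-np.sum((x - y) ** 2) / (2 * ell**2))

    total = 0.0
    for x in X:
        for y in X:
            total += stein(lambda z: stein(k_sec(z), y), x)
    return total / X.shape[0] ** 2


class TestExactKSD:
    def test_matches_nested_finite_differences(self, ou_fixture, rng):
        """The closed-form double-Stein kernel agrees with nested finite
        differences of the RBF kernel."""
        model, D = ou_fixture["model"], ou_fixture["diffusion"]
        ell = 1.2
        theta = np.array([-1.5])
        X = rng.standard_normal((4, 2))
        oracle = nested_fd_double_stein(X, theta, ell, model, D.constant_D)
        val = dy.exact_ksd(X, theta, ell, model, D)
        assert np.isclose(val, oracle, rtol=1e-4, atol=1e-6)

    def test_nonnegative_for_random_parameters(self, rng):
        model, data = _ou_data(60, seed=4)
        D = dy.constant_diffusion(1.0, dim=2)
        for _ in range(5):
            th = rng.standard_normal(1) * 3
            assert dy.exact_ksd(data, th, 1.0, model, D) >= -1e-10

    def test_oracle_cap_enforced(self, rng):
        model = dy.ou_affine()
        X = rng.standard_normal((51, 2))
        D = dy.constant_diffusion(1.0, dim=2)
        with pytest.raises(OracleSizeError, match="global_loss"):
            dy.exact_ksd(X, [-2.0], 1.0, model, D, max_n=50)

    def test_rff_loss_converges_to_exact(self):
        """|global_loss - exact_ksd| / exact_ksd shrinks as m grows."""
        model, data = _ou_data(50, seed=6, theta=-1.0)
        D = dy.constant_diffusion(1.0, dim=2)
        ell = dy.median_lengthscale(data)
        theta = np.array([-2.5])  # off the truth so the KSD is macroscopic
        exact = dy.exact_ksd(data, theta, ell, model, D)
        med_err = []
        for m in (100, 1000, 10_000):
            errs = []
            for seed in range(5):
                basis = dy.sample_rff(m, 2, ell, seed=seed)
                loss = dy.global_loss(data, theta, basis, model, D)
                errs.append(abs(loss - exact) / exact)
            med_err.append(np.median(errs))
        assert med_err[0] > med_err[1] > med_err[2]


class TestAssembleGlobalSystem:
    def test_defining_identity(self, random_affine_model, rng):
        """mean Stein feature == -sqrt(2/m) (A theta - b), hence
        global_loss == (2/m) ||A theta - b||^2."""
        model = random_affine_model
        D = dy.constant_diffusion(np.diag([0.5, 1.0, 0.2]))
        X = rng.standard_normal((40, 3))
        basis = dy.sample_rff(96, 3, 1.1, seed=8)
        system = dy.assemble_global_system(X, basis, model, D)
        for _ in range(5):
            th = rng.standard_normal(4)
            g = dy.mean_stein_feature(X, th, basis, model, D)
            assert np.allclose(
                g, -np.sqrt(2.0 / 96) * (system.A @ th - system.b), atol=1e-12
            )
            loss = dy.global_loss(X, th, basis, model, D)
            assert np.isclose(
                loss, 2.0 / 96 * np.sum((system.A @ th - system.b) ** 2), rtol=1e-10
            )

    def test_factored_assembly_matches_dense(self, rng):
        """The sparse-column fast path gives the same system as dense U."""
        model = dy.lorenz_affine()
        import dataclasses

        dense_model = dataclasses.replace(model, structure=None)
        X = rng.standard_normal((200, 3)) * 5
        D = dy.constant_diffusion(1.0, dim=3)
        basis = dy.sample_rff(128, 3, 4.0, seed=1)
        s_fast = dy.assemble_global_system(X, basis, model, D)
        s_dense = dy.assemble_global_system(X, basis, dense_model, D)
        assert np.allclose(s_fast.A, s_dense.A, atol=1e-12)
        assert np.allclose(s_fast.b, s_dense.b, atol=1e-12)

    def test_zero_fixed_field_zero_diffusion_gives_zero_rhs(self, rng):
        model = dy.ou_affine(fixed_mat=np.zeros((2, 2)))
        X = rng.standard_normal((30, 2))
        basis = dy.sample_rff(64, 2, 1.0, seed=2)
        system = dy.assemble_global_system(
            X, basis, model, dy.constant_diffusion(0.0, dim=2)
        )
        assert np.allclose(system.b, 0.0)
        assert np.allclose(system.A @ np.zeros(1), system.b)


class TestMinimizeGlobal:
    def test_affine_matches_linear_solve(self):
        model, data = _ou_data(500, seed=9)
        D = dy.constant_diffusion(1.0, dim=2)
        basis = dy.sample_rff(256, 2, 1.5, seed=9)
        system = dy.assemble_global_system(data, basis, model, D)
        direct = dy.ridge_solve(system, 0.0).theta_hat
        th = dy.minimize_global(data, basis, model, D, theta0=np.array([0.0]))
        assert np.allclose(th, direct, atol=1e-5)

    def test_start_at_solution_stays(self):
        model, data = _ou_data(300, seed=10)
        D = dy.constant_diffusion(1.0, dim=2)
        basis = dy.sample_rff(128, 2, 1.5, seed=10)
        system = dy.assemble_global_system(data, basis, model, D)
        sol = dy.ridge_solve(system, 0.0).theta_hat
        th = dy.minimize_global(data, basis, model, D, theta0=sol)
        assert np.allclose(th, sol, atol=1e-8)

    def test_nonaffine_wrapper_converges(self):
        aff, data = _ou_data(2000, seed=11)
        D = dy.constant_diffusion(1.0, dim=2)
        generic = dy.ParametricDrift(
            dim_state=2, dim_params=1,
            drift=lambda x, th: aff.drift(x, th),
            divergence=lambda x, th: aff.divergence(x, th),
        )
        basis = dy.sample_rff(256, 2, 1.5, seed=11)
        th = dy.minimize_global(data, basis, generic, D, theta0=np.array([-0.5]))
        direct = dy.ridge_solve(
            dy.assemble_global_system(data, basis, aff, D), 0.0
        ).theta_hat
        assert np.allclose(th, direct, atol=1e-4)
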