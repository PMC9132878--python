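"""GP-emulator tests: kernel values, an independent dense linear-algebra
oracle, an sklearn cross-check, sampling moments and the Q^2 metric."""

import numpy as np
import pytest

from lvuq.emulator import (GPEmulator, GPHyperparameters, MultiOutputEmulator,
                           ard_se_kernel, q2)


def dense_gp_oracle(Xtr, ytr, Xte, hyp):
    """Textbook dense GP posterior: mu = Ks^T K^-1 y,
    Sigma = Kss - Ks^T K^-1 Ks, written independently of the implementation
    under test (explicit inverse, loops over entries)."""
    def k(a, b):
        return hyp.sigma_f ** 2 * np.exp(
            -0.5 * np.sum((a - b) ** 2 / hyp.lengthscales ** 2))

    n, t = len(Xtr), len(Xte)
    K = np.array([[k(Xtr[i], Xtr[j]) for j in range(n)] for i in range(n)])
    K += hyp.eta ** 2 * np.eye(n)
    Ks = np.array([[k(Xtr[i], Xte[j]) for j in range(t)] for i in range(n)])
    Kss = np.array([[k(Xte[i], Xte[j]) for j in range(t)] for i in range(t)])
    Kinv = np.linalg.inv(K)
    return Ks.T @ Kinv @ ytr, Kss - Ks.T @ Kinv @ Ks


class TestKernel:
    HYP = GPHyperparameters(sigma_f=1.3, lengthscales=np.array([1.0, 2.0]),
                            eta=0.1)

    def test_same_point_value(self):
        x = np.array([[0.4, 0.7]])
        K = ard_se_kernel(x, x, self.HYP, same_points=True)
        assert K[0, 0] == pytest.approx(1.3 ** 2 + 0.1 ** 2)

    def test_decay_to_zero(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[100.0, 0.0]])
        assert ard_se_kernel(a, b, self.HYP)[0, 0] < 1e-12

    def test_unit_case_exact_value(self):
        hyp = GPHyperparameters(1.0, np.array([1.0, 1.0]), 1e-12)
        a = np.array([[0.0, 0.0]])
        b = np.array([[1.0, 1.0]])  # squared distance 2
        assert ard_se_kernel(a, b, hyp)[0, 0] == pytest.approx(np.exp(-1.0))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            ard_se_kernel(np.ones((2, 3)), np.ones((2, 3)), self.HYP)


class TestQ2:
    def test_perfect_prediction(self):
        assert q2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert q2(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_arithmetic_example(self):
        assert q2([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_constant_truth_errors(self):
        with pytest.raises(ValueError, match="constant"):
            q2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPredictOracle:
    def test_matches_dense_oracle_small_problems(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            n, t, d = rng.integers(5, 20), 6, 2
            Xtr = rng.uniform(-2, 2, (n, d))
            ytr = np.sin(Xtr[:, 0]) + 0.5 * Xtr[:, 1]
            Xte = rng.uniform(-2, 2, (t, d))
            hyp = GPHyperparameters(sigma_f=float(rng.uniform(0.5, 2.0)),
                                    lengthscales=rng.uniform(0.5, 2.0, d),
                                    eta=0.05)
            gp = GPEmulator()
            # install fixed hyperparameters and factorization manually
            gp.log_mask_ = np.zeros(d, dtype=bool)
            gp.x_mean_, gp.x_std_ = np.zeros(d), np.ones(d)
            gp.y_mean_, gp.y_std_ = 0.0, 1.0
            gp.X_raw_, gp.Xt_ = Xtr, Xtr
            gp.yt_ = ytr
            gp.hyp_ = hyp
            from lvuq.emulator import _chol_with_jitter
            from scipy import linalg
            K = ard_se_kernel(Xtr, Xtr, hyp, same_points=True)
            gp.L_ = _chol_with_jitter(K)
            gp.alpha_ = linalg.cho_solve((gp.L_, True), ytr)
            gp.n_features_in_ = d
            mu, cov = gp.predict(Xte, return_cov=True)
            mu_o, cov_o = dense_gp_oracle(Xtr, ytr, Xte, hyp)
            assert np.abs(mu - mu_o).max() < 1e-8
            assert np.abs(cov - cov_o).max() < 1e-8

    def test_toy_hand_check_three_points(self):
        # 3 isolated training points, nearly-zero nugget: the posterior mean
        # at a training point recovers the datum
        Xtr = np.array([[0.0], [1.0], [2.5]])
        ytr = np.array([1.0, -1.0, 0.5])
        hyp = GPHyperparameters(1.0, np.array([0.8]), 1e-6)
        mu_o, cov_o = dense_gp_oracle(Xtr, ytr, np.array([[1.0]]), hyp)
        assert mu_o[0] == pytest.approx(-1.0, abs=1e-4)
        assert cov_o[0, 0] < 1e-6


class TestFit:
    def test_interpolates_with_small_nugget(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 4, (40, 2))
        y = np.cos(X[:, 0]) * X[:, 1]
        gp = GPEmulator(n_restarts=2, random_state=0).fit(X, y)
        pred = gp.predict(X[:5])
        assert np.abs(pred - y[:5]).max() < 1e-3

    def test_duplicate_training_point_absorbed_by_nugget(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (15, 1))
        X[1] = X[0]
        y = rng.standard_normal(15)
        gp = GPEmulator(n_restarts=1, random_state=0).fit(X, y)
        assert np.isfinite(gp.predict(np.array([[0.5]]))[0])

    def test_lml_improves_over_init(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 4, (60, 2))
        y = np.sin(X).sum(axis=1)
        gp = GPEmulator(n_restarts=2, random_state=1).fit(X, y)
        z0 = np.concatenate([[0.0], np.zeros(2), [np.log(0.05)]])
        yt = (y - y.mean()) / y.std()
        Xt = gp._transform_X(X)
        nll0, _ = GPEmulator._nll_and_grad(z0, Xt, yt)
        z_fit = np.log(np.concatenate([[gp.hyp_.sigma_f],
                                       gp.hyp_.lengthscales, [gp.hyp_.eta]]))
        nll_fit, _ = GPEmulator._nll_and_grad(z_fit, Xt, yt)
        assert nll_fit <= nll0 + 1e-9

    def test_lengthscale_recovery_within_factor_two(self):
        # data from a known GP; ARD lengthscales recovered to a factor of 2
        rng = np.random.default_rng(4)
        true = GPHyperparameters(1.0, np.array([0.5, 2.0]), 0.05)
        X = rng.uniform(0, 4, (200, 2))
        K = ard_se_kernel(X, X, true, same_points=True)
        y = np.linalg.cholesky(K + 1e-10 * np.eye(200)) \
            @ rng.standard_normal(200)
        gp = GPEmulator(n_restarts=3, random_state=0).fit(X, y)
        # compare in standardized input units
        ls_true_std = true.lengthscales / X.std(axis=0)
        ratio = gp.hyp_.lengthscales / ls_true_std
        assert np.all((ratio > 0.5) & (ratio < 2.0))

    def test_nll_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 2, (25, 2))
        y = rng.standard_normal(25)
        z = np.array([0.2, -0.3, 0.4, np.log(0.1)])
        f0, g = GPEmulator._nll_and_grad(z, X, y)
        for k in range(z.size):
            e = np.eye(z.size)[k] * 1e-6
            fp, _ = GPEmulator._nll_and_grad(z + e, X, y)
            fm, _ = GPEmulator._nll_and_grad(z - e, X, y)
            assert g[k] == pytest.approx((fp - fm) / 2e-6, rel=1e-4, abs=1e-6)

    def test_sklearn_cross_check(self):
        # independent implementation: sklearn GP with the same kernel family
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, \
            WhiteKernel
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 4, (60, 2))
        y = np.sin(X[:, 0]) + 0.2 * X[:, 1] ** 2
        gp = GPEmulator(n_restarts=3, random_state=0).fit(X, y)
        hyp = gp.hyp_
        sk_kernel = (ConstantKernel(hyp.sigma_f ** 2, "fixed")
                     * RBF(hyp.lengthscales, "fixed")
                     + WhiteKernel(hyp.eta ** 2, "fixed"))
        sk = GaussianProcessRegressor(kernel=sk_kernel, alpha=0.0,
                                      optimizer=None, normalize_y=False)
        Xt = gp._transform_X(X)
        yt = (y - gp.y_mean_) / gp.y_std_
        sk.fit(Xt, yt)
        Xq = rng.uniform(0, 4, (10, 2))
        mu_sk = sk.predict(gp._transform_X(Xq))
        mu = gp.predict(Xq, standardized=True)
        assert np.abs(mu - mu_sk).max() < 1e-5

    def test_destandardization_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 4, (50, 2))
        y = np.sin(X[:, 0]) + X[:, 1]
        Xq = rng.uniform(0, 4, (8, 2))
        p1 = GPEmulator(n_restarts=2, random_state=0).fit(X, y).predict(Xq)
        p2 = GPEmulator(n_restarts=2, random_state=0).fit(
            X, 10.0 * y + 100.0).predict(Xq)
        assert np.abs((p2 - 100.0) / 10.0 - p1).max() < 1e-4

    def test_variance_bounded_by_prior(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 4, (30, 2))
        y = np.sin(X[:, 0])
        gp = GPEmulator(n_restarts=1, random_state=0).fit(X, y)
        _, cov = gp.predict(rng.uniform(-10, 14, (20, 2)), return_cov=True,
                            standardized=True)
        assert np.all(np.diag(cov) <= gp.hyp_.sigma_f ** 2
                      + gp.hyp_.eta ** 2 + 1e-9)

    def test_rejects_tiny_training_sets(self):
        with pytest.raises(ValueError, match="at least 10"):
            GPEmulator().fit(np.ones((4, 2)), np.ones(4))


class TestSampling:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 4, (50, 2))
        y = np.sin(X[:, 0]) + 0.3 * X[:, 1]
        return GPEmulator(n_restarts=2, random_state=0).fit(X, y)

    def test_seed_reproducibility(self, fitted):
        Xq = np.array([[1.0, 2.0], [3.0, 0.5]])
        s1 = fitted.sample_y(Xq, 5, random_state=42)
        s2 = fitted.sample_y(Xq, 5, random_state=42)
        assert np.array_equal(s1, s2)

    def test_sample_mean_matches_posterior_mean(self, fitted):
        Xq = np.array([[2.0, 2.0]])
        draws = fitted.sample_y(Xq, 10_000, random_state=0)
        mu, std = fitted.predict(Xq, return_std=True)
        se = std[0] / np.sqrt(10_000)
        assert abs(draws.mean() - mu[0]) < 4 * max(se, 1e-12)

    def test_rff_exchangeable_with_dense(self, fitted):
        # decoupled pathwise draws must match dense draws in distribution
        Xq = np.array([[0.5, 1.0], [2.0, 2.0], [3.5, 3.0]])
        d = fitted.sample_y(Xq, 4000, random_state=1, method="dense")
        r = fitted.sample_y(Xq, 4000, random_state=2, method="rff",
                            n_features=4096)
        assert np.abs(d.mean(0) - r.mean(0)).max() < 0.02
        assert np.abs(d.std(0) - r.std(0)).max() < 0.02


class TestMultiOutput:
    def test_joint_grad_matches_per_output(self):
        rng = np.random.default_rng(10)
        X = np.column_stack([np.exp(rng.uniform(-1, 1, (40, 1))),
                             rng.uniform(0, 4, (40, 1))])
        Y = np.column_stack([np.log(X[:, 0]) + X[:, 1],
                             X[:, 1] ** 2 - np.log(X[:, 0])])
        mo = MultiOutputEmulator(["u", "v"], log_dims=[0], n_restarts=2)
        mo.fit(X, Y, random_state=0)
        x0 = np.array([1.3, 2.0])
        mu, g = mo.joint_mean_grad(x0)
        for j in range(2):
            mu_j, g_j = mo[j].predict_mean_grad(x0)
            assert mu[j] == pytest.approx(mu_j, rel=1e-7, abs=1e-7)
            assert np.abs(g[j] - g_j).max() < 1e-7

    def test_mean_grad_matches_finite_differences(self):
        rng = np.random.default_rng(11)
        X = np.column_stack([np.exp(rng.uniform(-1, 1, (40, 1))),
                             rng.uniform(0, 4, (40, 1))])
        y = np.sin(2.0 * np.log(X[:, 0])) * X[:, 1] \
            + 0.01 * rng.standard_normal(len(X))
        mo = MultiOutputEmulator(["u"], log_dims=[0], n_restarts=2)
        mo.fit(X, y.reshape(-1, 1), random_state=0)
        x0 = np.array([1.3, 2.0])
        _, g = mo.joint_mean_grad(x0)
        for k in range(2):
            e = np.eye(2)[k] * 1e-4
            fd = (mo.predict((x0 + e).reshape(1, -1))[0, 0]
                  - mo.predict((x0 - e).reshape(1, -1))[0, 0]) / 2e-4
            assert g[0, k] == pytest.approx(fd, rel=1e-3, abs=1e-5)

    def test_serialization_roundtrip(self, tmp_path):
        rng = np.random.default_rng(12)
        X = rng.uniform(0.5, 4, (30, 2))
        Y = np.column_stack([X.sum(axis=1), X.prod(axis=1)])
        mo = MultiOutputEmulator(["s", "p"], log_dims=[0], n_restarts=1)
        mo.fit(X, Y, random_state=0)
        path = tmp_path / "emu.json"
        mo.save(path)
        mo2 = MultiOutputEmulator.load(path)
        Xq = rng.uniform(0.5, 4, (5, 2))
        assert np.abs(mo.predict(Xq) - mo2.predict(Xq)).max() < 1e-10
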