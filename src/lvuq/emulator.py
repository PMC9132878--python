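"""Gaussian-process surrogate regression for scalar simulator outputs.

One independent zero-mean GP per scalar output, with an automatic-relevance-
determination squared-exponential kernel plus nugget,

    k(x_i, x_j) = sigma_f^2 exp(-1/2 sum_k (x_ik - x_jk)^2 / l_k^2)
                  + eta^2 delta_ij.

Inputs are log-transformed on the material-constant dimensions (the response
varies much faster for soft configurations; the log makes it more
stationary) and then standardized per dimension; outputs are standardized to
mean zero / unit variance before training, matching the zero prior mean.
Hyperparameters are point estimates maximizing the log marginal likelihood
(multi-restart L-BFGS-B with analytic gradients).

The estimator follows scikit-learn conventions (``fit`` / ``predict`` /
``sample_y`` / ``get_params``) and composes with sklearn model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GPHyperparameters",
    "GPEmulator",
    "MultiOutputEmulator",
    "ard_se_kernel",
    "q2",
]


@dataclass(frozen=True)
class GPHyperparameters:
    """Kernel hyperparameters: amplitude sigma_f, per-dimension lengthscales
    (both in standardized units) and nugget standard deviation eta."""

    sigma_f: float
    lengthscales: np.ndarray
    eta: float

    def __post_init__(self):
        ls = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        object.__setattr__(self, "lengthscales", ls)
        if self.sigma_f <= 0 or self.eta <= 0 or np.any(ls <= 0):
            raise ValueError("all hyperparameters must be strictly positive")


def ard_se_kernel(Xa, Xb, hyp: GPHyperparameters, same_points: bool = False) -> np.ndarray:
    """ARD squared-exponential kernel matrix between row sets.

    ``same_points=True`` adds the nugget eta^2 on the diagonal (the
    Kronecker delta applies when x_i and x_j are the same data point).
    """
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    if Xa.shape[1] != hyp.lengthscales.size or Xb.shape[1] != Xa.shape[1]:
        raise ValueError("input dimension does not match lengthscales")
    A = Xa / hyp.lengthscales
    B = Xb / hyp.lengthscales
    d2 = (np.sum(A * A, axis=1)[:, None] + np.sum(B * B, axis=1)[None, :]
          - 2.0 * A @ B.T)
    K = hyp.sigma_f ** 2 * np.exp(-0.5 * np.maximum(d2, 0.0))
    if same_points:
        if Xa.shape[0] != Xb.shape[0]:
            raise ValueError("same_points requires matching row counts")
        K[np.diag_indices_from(K)] += hyp.eta ** 2
    return K


def q2(f_true, f_pred) -> float:
    """Out-of-sample coefficient of determination.

    Q^2 = 1 - SSE/SST with SST taken about the mean of the *test* outputs:
    1 for perfect prediction, 0 for predicting the test mean.
    """
    f_true = np.asarray(f_true, dtype=float).ravel()
    f_pred = np.asarray(f_pred, dtype=float).ravel()
    if f_true.size != f_pred.size or f_true.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    sst = float(np.sum((f_true - f_true.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("test outputs are constant; Q^2 undefined")
    return 1.0 - float(np.sum((f_true - f_pred) ** 2)) / sst


def _chol_with_jitter(K: np.ndarray, max_tries: int = 6):
    jitter = 0.0
    base = np.mean(np.diag(K))
    for t in range(max_tries):
        try:
            return linalg.cholesky(K + jitter * np.eye(K.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter = base * 10.0 ** (t - 8)
    raise linalg.LinAlgError("covariance not positive definite after jitter "
                             "escalation")


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Square-root factor of a (numerically) PSD matrix for sampling:
    Cholesky when possible, eigen-clipped factor otherwise."""
    try:
        return linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]), lower=True)
    except linalg.LinAlgError:
        w, V = linalg.eigh(cov)
        return V * np.sqrt(np.maximum(w, 0.0))


class GPEmulator(RegressorMixin, BaseEstimator):
    """Zero-mean GP regressor with ARD-SE kernel and optimized nugget.

    Parameters
    ----------
    log_dims : sequence of int or None
        Input columns that are log-transformed before standardization
        (the material-constant dimensions).
    n_restarts : int
        Marginal-likelihood optimizer restarts (first start is a fixed
        heuristic; the rest are seeded perturbations).
    nugget_floor : float
        Lower bound for eta (standardized output units).
    max_opt_subset : int or None
        If the training set is larger, hyperparameters are optimized on a
        seeded random subset of this size and the model then conditions on
        the full set.  ``None`` disables subsetting.
    maxiter : int
        L-BFGS-B iteration cap per restart.
    """

    def __init__(self, log_dims=None, n_restarts: int = 5,
                 nugget_floor: float = 1e-6, max_opt_subset: int | None = 512,
                 maxiter: int = 100, random_state: int | None = None):
        self.log_dims = log_dims
        self.n_restarts = n_restarts
        self.nugget_floor = nugget_floor
        self.max_opt_subset = max_opt_subset
        self.maxiter = maxiter
        self.random_state = random_state

    # -- transforms ---------------------------------------------------------

    def _transform_X(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = X.copy()
        if len(self.log_mask_.nonzero()[0]):
            with np.errstate(divide="raise", invalid="raise"):
                try:
                    Z[:, self.log_mask_] = np.log(X[:, self.log_mask_])
                except FloatingPointError as err:
                    raise ValueError("non-positive value in a log-transformed "
                                     "input dimension") from err
        return (Z - self.x_mean_) / self.x_std_

    def _grad_chain(self, X: np.ndarray) -> np.ndarray:
        """d(transformed)/d(raw) per row and dimension."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        J = np.ones_like(X) / self.x_std_
        J[:, self.log_mask_] /= X[:, self.log_mask_]
        return J

    # -- marginal likelihood ------------------------------------------------

    @staticmethod
    def _nll_and_grad(z: np.ndarray, Xt: np.ndarray, yt: np.ndarray):
        n, d = Xt.shape
        sigma_f, eta = np.exp(z[0]), np.exp(z[-1])
        ls = np.exp(z[1:-1])
        A = Xt / ls
        sq = np.sum(A * A, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * A @ A.T
        np.maximum(d2, 0.0, out=d2)
        E = np.exp(-0.5 * d2)
        K = sigma_f ** 2 * E
        K[np.diag_indices(n)] += eta ** 2
        try:
            L = linalg.cholesky(K, lower=True)
        except linalg.LinAlgError:
            return 1e10, np.zeros_like(z)
        alpha = linalg.cho_solve((L, True), yt)
        nll = (0.5 * yt @ alpha + np.sum(np.log(np.diag(L)))
               + 0.5 * n * np.log(2.0 * np.pi))
        Kinv = linalg.cho_solve((L, True), np.eye(n))
        W = Kinv - np.outer(alpha, alpha)  # 0.5 tr(W dK) gives d(nll)
        grad = np.empty_like(z)
        WK = W * (sigma_f ** 2 * E)
        grad[0] = np.sum(WK)  # d/dlog sigma_f: dK = 2 sigma_f^2 E
        for k in range(d):
            diff = Xt[:, k][:, None] - Xt[None, :, k]
            grad[1 + k] = 0.5 * np.sum(WK * (diff * diff) / ls[k] ** 2)
        grad[-1] = eta ** 2 * np.trace(W)
        return nll, grad

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        if n < 10:
            raise ValueError("need at least 10 training points")
        if y.size != n:
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("training data must be finite")

        mask = np.zeros(d, dtype=bool)
        if self.log_dims is not None:
            mask[np.asarray(self.log_dims, dtype=int)] = True
        self.log_mask_ = mask

        Z = X.copy()
        Z[:, mask] = np.log(Z[:, mask])
        self.x_mean_ = Z.mean(axis=0)
        std = Z.std(axis=0)
        self.x_std_ = np.where(std > 0, std, 1.0)
        self.y_mean_ = float(y.mean())
        ystd = float(y.std())
        self.y_std_ = ystd if ystd > 0 else 1.0

        self.X_raw_ = X
        Xt = self._transform_X(X)
        yt = (y - self.y_mean_) / self.y_std_
        self.Xt_, self.yt_ = Xt, yt

        rng = np.random.default_rng(self.random_state)
        if self.max_opt_subset is not None and n > self.max_opt_subset:
            idx = rng.choice(n, size=self.max_opt_subset, replace=False)
            Xo, yo = Xt[idx], yt[idx]
        else:
            Xo, yo = Xt, yt

        lo = np.log(self.nugget_floor)
        # lengthscales in standardized units: 1e2 is already effectively
        # constant over the design; larger values only hurt conditioning
        bounds = ([(np.log(1e-3), np.log(1e3))]
                  + [(np.log(1e-2), np.log(1e2))] * d
                  + [(lo, np.log(1.0))])
        z0 = np.concatenate([[0.0], np.zeros(d), [np.log(0.05)]])
        best = None
        for r in range(max(1, self.n_restarts)):
            z_init = z0 if r == 0 else z0 + rng.uniform(-1.0, 1.0, z0.size)
            z_init = np.clip(z_init, [b[0] for b in bounds],
                             [b[1] for b in bounds])
            res = optimize.minimize(
                self._nll_and_grad, z_init, args=(Xo, yo), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.maxiter})
            if best is None or res.fun < best.fun:
                best = res
        z = best.x
        self.hyp_ = GPHyperparameters(sigma_f=float(np.exp(z[0])),
                                      lengthscales=np.exp(z[1:-1]),
                                      eta=float(np.exp(z[-1])))
        self.log_marginal_likelihood_ = -float(best.fun) if (
            self.max_opt_subset is None or n <= self.max_opt_subset) else None

        K = ard_se_kernel(Xt, Xt, self.hyp_, same_points=True)
        self.L_ = _chol_with_jitter(K)
        self.alpha_ = linalg.cho_solve((self.L_, True), yt)
        self.n_features_in_ = d
        return self

    # -- prediction ---------------------------------------------------------

    def predict(self, X, return_std: bool = False, return_cov: bool = False,
                standardized: bool = False):
        check_is_fitted(self, "alpha_")
        Xs = self._transform_X(X)
        Ks = ard_se_kernel(self.Xt_, Xs, self.hyp_)
        mu = Ks.T @ self.alpha_
        out_mu = mu if standardized else self.y_mean_ + self.y_std_ * mu
        if not (return_std or return_cov):
            return out_mu
        V = linalg.solve_triangular(self.L_, Ks, lower=True)
        if return_cov:
            Kss = ard_se_kernel(Xs, Xs, self.hyp_)
            cov = Kss - V.T @ V
            cov = 0.5 * (cov + cov.T)
            if not standardized:
                cov = self.y_std_ ** 2 * cov
            return out_mu, cov
        var = np.maximum(self.hyp_.sigma_f ** 2 - np.sum(V * V, axis=0), 0.0)
        std = np.sqrt(var)
        if not standardized:
            std = self.y_std_ * std
        return out_mu, std

    def predict_mean_grad(self, x):
        """Posterior mean and its gradient w.r.t. the raw (natural-unit)
        input, at a single point."""
        check_is_fitted(self, "alpha_")
        x = np.asarray(x, dtype=float).reshape(1, -1)
        xs = self._transform_X(x)
        diffs = self.Xt_ - xs  # (n, d)
        kvec = (self.hyp_.sigma_f ** 2
                * np.exp(-0.5 * np.sum((diffs / self.hyp_.lengthscales) ** 2,
                                       axis=1)))
        mu = float(self.alpha_ @ kvec)
        gt = (self.alpha_ * kvec) @ (diffs / self.hyp_.lengthscales ** 2)
        grad = self.y_std_ * gt * self._grad_chain(x)[0]
        return self.y_mean_ + self.y_std_ * mu, grad

    def sample_y(self, X, n_samples: int = 250, random_state=None,
                 method: str = "dense", n_features: int = 1024,
                 standardized: bool = False) -> np.ndarray:
        """Draw joint posterior function samples over the rows of ``X``.

        ``method='dense'`` factorizes the full predictive covariance;
        ``method='rff'`` uses decoupled pathwise (Matheron) sampling with a
        random-Fourier-feature prior, scaling to designs far beyond dense
        feasibility.  Returns an (n_samples, len(X)) array.
        """
        check_is_fitted(self, "alpha_")
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        rng = np.random.default_rng(random_state)
        Xs = self._transform_X(X)
        if method == "dense":
            mu, cov = self.predict(X, return_cov=True, standardized=True)
            Lc = _psd_factor(cov)
            draws = mu + rng.standard_normal((n_samples, Xs.shape[0])) @ Lc.T
        elif method == "rff":
            draws = self._sample_rff(Xs, n_samples, rng, n_features)
        else:
            raise ValueError("method must be 'dense' or 'rff'")
        if not standardized:
            draws = self.y_mean_ + self.y_std_ * draws
        return draws

    def _sample_rff(self, Xs, n_samples, rng, n_features):
        hyp = self.hyp_
        d = Xs.shape[1]
        omega = rng.standard_normal((n_features, d)) / hyp.lengthscales
        phase = rng.uniform(0.0, 2.0 * np.pi, n_features)
        scale = hyp.sigma_f * np.sqrt(2.0 / n_features)

        def phi(Z):
            return scale * np.cos(Z @ omega.T + phase)

        Phi_star = phi(Xs)                      # (T, M)
        Phi_train = phi(self.Xt_)               # (N, M)
        w = rng.standard_normal((n_samples, n_features))
        f_star_prior = w @ Phi_star.T           # (S, T)
        f_train_prior = w @ Phi_train.T         # (S, N)
        eps = hyp.eta * rng.standard_normal(f_train_prior.shape)
        resid = self.yt_[None, :] - f_train_prior - eps
        V = linalg.cho_solve((self.L_, True), resid.T)   # (N, S)
        Ks = ard_se_kernel(self.Xt_, Xs, hyp)            # (N, T)
        return f_star_prior + (Ks.T @ V).T


class MultiOutputEmulator:
    """Bank of independent :class:`GPEmulator` s sharing one input design.

    Provides a vectorized joint mean/gradient evaluation across all outputs
    at a single point (the hot path of gradient-based posterior sampling).
    """

    def __init__(self, output_names, **gp_kwargs):
        self.output_names = list(output_names)
        self.gp_kwargs = gp_kwargs
        self.emulators_: list[GPEmulator] = []

    def fit(self, X, Y, random_state: int | None = None):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[1] != len(self.output_names):
            raise ValueError("Y columns must match output_names")
        self.emulators_ = []
        for j in range(Y.shape[1]):
            kw = dict(self.gp_kwargs)
            if random_state is not None:
                kw.setdefault("random_state", random_state + j)
            self.emulators_.append(GPEmulator(**kw).fit(X, Y[:, j]))
        self._build_stack()
        return self

    def _build_stack(self):
        ems = self.emulators_
        self._Xt = ems[0].Xt_
        self._inv_l2 = np.array([1.0 / e.hyp_.lengthscales ** 2 for e in ems])
        self._sigf2 = np.array([e.hyp_.sigma_f ** 2 for e in ems])
        self._alpha = np.array([e.alpha_ for e in ems])
        self._ymean = np.array([e.y_mean_ for e in ems])
        self._ystd = np.array([e.y_std_ for e in ems])
        self._ref = ems[0]
        self._asig = self._alpha * self._sigf2[:, None]

    def __getitem__(self, key) -> GPEmulator:
        if isinstance(key, str):
            key = self.output_names.index(key)
        return self.emulators_[key]

    def __len__(self):
        return len(self.emulators_)

    def predict(self, X) -> np.ndarray:
        """(n, K) matrix of posterior means."""
        return np.column_stack([e.predict(X) for e in self.emulators_])

    def joint_mean_grad(self, x):
        """All-output posterior means and raw-space gradients at one point.

        Returns ``(mu (K,), grad (K, D))``.
        """
        ref = self._ref
        x = np.asarray(x, dtype=float).ravel()
        xt = x.copy()
        mask = ref.log_mask_
        xt[mask] = np.log(xt[mask])
        xt = (xt - ref.x_mean_) / ref.x_std_
        diffs = self._Xt - xt                          # (N, D)
        d2 = (diffs * diffs) @ self._inv_l2.T          # (N, K)
        ak = self._asig.T * np.exp(-0.5 * d2)          # (N, K)
        mu = self._ymean + self._ystd * ak.sum(axis=0)
        gt = (ak.T @ diffs) * self._inv_l2             # (K, D)
        chain = 1.0 / ref.x_std_.copy()
        chain[mask] /= x[mask]
        grad = (self._ystd[:, None] * gt) * chain[None, :]
        return mu, grad

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        ems = []
        for name, e in zip(self.output_names, self.emulators_):
            ems.append({
                "output": name,
                "log_dims": np.nonzero(e.log_mask_)[0].tolist(),
                "x_mean": e.x_mean_.tolist(), "x_std": e.x_std_.tolist(),
                "y_mean": e.y_mean_, "y_std": e.y_std_,
                "sigma_f": e.hyp_.sigma_f,
                "lengthscales": e.hyp_.lengthscales.tolist(),
                "eta": e.hyp_.eta,
                "X_raw": e.X_raw_.tolist(), "yt": e.yt_.tolist(),
            })
        return {"format": "lvuq-emulator-v1", "emulators": ems}

    @classmethod
    def from_dict(cls, d: dict) -> "MultiOutputEmulator":
        if d.get("format") != "lvuq-emulator-v1":
            raise ValueError("unrecognized emulator archive format")
        self = cls([e["output"] for e in d["emulators"]])
        for rec in d["emulators"]:
            e = GPEmulator(log_dims=rec["log_dims"])
            X = np.asarray(rec["X_raw"], dtype=float)
            e.log_mask_ = np.zeros(X.shape[1], dtype=bool)
            e.log_mask_[rec["log_dims"]] = True
            e.x_mean_ = np.asarray(rec["x_mean"])
            e.x_std_ = np.asarray(rec["x_std"])
            e.y_mean_, e.y_std_ = rec["y_mean"], rec["y_std"]
            e.X_raw_ = X
            e.Xt_ = e._transform_X(X)
            e.yt_ = np.asarray(rec["yt"])
            e.hyp_ = GPHyperparameters(rec["sigma_f"],
                                       np.asarray(rec["lengthscales"]),
                                       rec["eta"])
            K = ard_se_kernel(e.Xt_, e.Xt_, e.hyp_, same_points=True)
            e.L_ = _chol_with_jitter(K)
            e.alpha_ = linalg.cho_solve((e.L_, True), e.yt_)
            e.n_features_in_ = X.shape[1]
            self.emulators_.append(e)
        self._build_stack()
        return self

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "MultiOutputEmulator":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
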