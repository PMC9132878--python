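"""Bayesian inverse uncertainty quantification of the reduced material
parameters.

The observation is one end-diastolic volume y0 (ml) and 24 segmental
circumferential strains y_1..y_24; the two-component Gaussian noise model
(volume variance sigma0^2 fixed, strain variance sigma_tilde^2 inferred)
gives the log-likelihood

    l = -1/2 log sigma0^2 - (y0 - f0(theta))^2 / (2 sigma0^2)
        - 24/2 log sigma_tilde^2
        - sum_i (y_i - f_i(theta))^2 / (2 sigma_tilde^2),

with f replaced by GP-emulator posterior means (a known bias source: the
emulator variance is not propagated).  Priors are uniform on the natural
parameter scale over the design bounds (and uniform on sigma_tilde over a
configurable interval); sampling runs in an unconstrained space via a
logit-of-log reparameterization whose Jacobian preserves those priors
exactly.  Convergence is monitored with the classic Gelman-Rubin potential
scale reduction factor over chains started from dispersed (Sobol) points;
identifiability is summarized by the inverse interquartile range (I-IQR)
of the natural-scale marginals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import qmc

from .design import REDUCED_NAMES, DESIGN_BOUNDS
from .emulator import MultiOutputEmulator
from .forward import N_SEGMENTS
from .nuts import nuts_chain

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationVector",
    "NoiseModel",
    "MCMCConfig",
    "PosteriorSamples",
    "ConvergenceReport",
    "log_likelihood",
    "make_log_posterior",
    "run_mcmc",
    "psrf",
    "iiqr",
    "run_iuq_battery",
    "IUQ_OUTPUT_NAMES",
]

#: Emulator outputs used for inference: volume then the 24 strains.
IUQ_OUTPUT_NAMES: tuple[str, ...] = ("LVV",) + tuple(
    f"eps_cc_{i}" for i in range(N_SEGMENTS))

#: Sampled-parameter labels (log scale).
PARAM_LABELS: tuple[str, ...] = ("log_a", "log_b", "log_a_f", "log_b_f",
                                 "log_sigma2_tilde")


@dataclass(frozen=True)
class ObservationVector:
    """Measured volume (ml) and 24 circumferential strains."""

    y0: float
    y_tilde: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y_tilde, dtype=float)
        if y.shape != (N_SEGMENTS,):
            raise ValueError(f"y_tilde must have {N_SEGMENTS} entries")
        object.__setattr__(self, "y_tilde", y)

    @classmethod
    def from_array(cls, arr) -> "ObservationVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (1 + N_SEGMENTS,):
            raise ValueError("expected 25 observation entries")
        return cls(y0=float(arr[0]), y_tilde=arr[1:])


@dataclass(frozen=True)
class NoiseModel:
    """Volume noise variance is fixed during inference (it multiplies a
    single measurement and is non-identifiable); the strain variance is
    inferred with a uniform prior on sigma_tilde over ``sigma_tilde_bounds``."""

    sigma0_sq: float = 25.0
    sigma_tilde_bounds: tuple[float, float] = (1e-4, 0.2)

    def __post_init__(self):
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be positive")
        lo, hi = self.sigma_tilde_bounds
        if not (0 < lo < hi):
            raise ValueError("invalid sigma_tilde bounds")


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 5
    n_warmup: int = 1000
    n_draws: int = 2000
    max_treedepth: int = 8
    target_accept: float = 0.8
    seed: int = 0
    theta_bounds: tuple[float, float] = DESIGN_BOUNDS["a"]
    psrf_threshold: float = 1.01


@dataclass(frozen=True)
class ConvergenceReport:
    psrf: dict
    threshold: float

    @property
    def max_psrf(self) -> float:
        return max(self.psrf.values())

    @property
    def converged(self) -> bool:
        return self.max_psrf < self.threshold


@dataclass
class PosteriorSamples:
    """Post-warmup draws: (chains, draws, 5) over (log a, log b, log a_f,
    log b_f, log sigma_tilde^2), with sampler metadata."""

    draws: np.ndarray
    param_labels: tuple = PARAM_LABELS
    edp: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def stacked(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def theta(self) -> np.ndarray:
        """Natural-scale material-parameter draws, (n_total, 4)."""
        return np.exp(self.stacked()[:, :4])

    def sigma_tilde_sq(self) -> np.ndarray:
        return np.exp(self.stacked()[:, 4])

    def marginal(self, name: str) -> np.ndarray:
        """Natural-scale marginal draws for a reduced parameter name."""
        idx = list(REDUCED_NAMES).index(name)
        return np.exp(self.stacked()[:, idx])

    def convergence(self, threshold: float = 1.01) -> ConvergenceReport:
        vals = {}
        for k, label in enumerate(self.param_labels):
            vals[label] = psrf(self.draws[:, :, k])
        return ConvergenceReport(psrf=vals, threshold=threshold)

    def to_frame(self) -> pd.DataFrame:
        c, n, d = self.draws.shape
        df = pd.DataFrame(self.stacked(), columns=list(self.param_labels))
        df.insert(0, "draw", np.tile(np.arange(n), c))
        df.insert(0, "chain", np.repeat(np.arange(c), n))
        return df


# -- reparameterization -----------------------------------------------------

def _sigmoid(z):
    return special.expit(z)


def _log_sigmoid(z):
    # log s(z) = -log(1 + e^{-z}), numerically stable both tails
    return -np.logaddexp(0.0, -np.asarray(z, dtype=float))


class _Reparam:
    """Unconstrained z -> (theta (4), sigma_tilde^2) with the exact Jacobian
    for a uniform prior on natural theta and on sigma_tilde."""

    def __init__(self, theta_bounds, sigma_bounds):
        lo, hi = theta_bounds
        self.la, self.lb = np.log(lo), np.log(hi)
        self.slo, self.shi = sigma_bounds

    def forward(self, z):
        s = _sigmoid(np.asarray(z, dtype=float))
        log_theta = self.la + (self.lb - self.la) * s[:4]
        theta = np.exp(log_theta)
        sig = self.slo + (self.shi - self.slo) * s[4]
        return theta, sig ** 2

    def log_jacobian_and_grad(self, z):
        """log |d(theta, sigma)/dz| plus its gradient in z.  Combined with a
        flat prior on (theta, sigma) this is the full log-prior term."""
        z = np.asarray(z, dtype=float)
        s = _sigmoid(z)
        ls, l1ms = _log_sigmoid(z), _log_sigmoid(-z)
        rng_t = self.lb - self.la
        log_theta = self.la + rng_t * s[:4]
        lj = float(np.sum(log_theta + np.log(rng_t) + ls[:4] + l1ms[:4]))
        lj += float(np.log(self.shi - self.slo) + ls[4] + l1ms[4])
        grad = np.empty(5)
        grad[:4] = rng_t * s[:4] * (1 - s[:4]) + (1 - 2 * s[:4])
        grad[4] = 1 - 2 * s[4]
        return lj, grad

    def z_of(self, theta, sigma_tilde):
        """Inverse map (used for dispersed chain starts)."""
        t = (np.log(np.asarray(theta, dtype=float)) - self.la) / (self.lb - self.la)
        u = (sigma_tilde - self.slo) / (self.shi - self.slo)
        vals = np.concatenate([t, [u]])
        vals = np.clip(vals, 1e-6, 1 - 1e-6)
        return np.log(vals) - np.log1p(-vals)


def log_likelihood(y: ObservationVector, theta: np.ndarray,
                   sigma_tilde_sq: float, emulators: MultiOutputEmulator,
                   noise: NoiseModel, edp: float, grad: bool = False):
    """Two-component Gaussian log-likelihood through the emulator means.

    ``theta`` is the natural-scale reduced parameter vector (a, b, a_f,
    b_f).  With ``grad=True`` also returns (d l/d theta (4,),
    d l/d sigma_tilde_sq).  Additive constants are omitted consistently.
    """
    theta = np.asarray(theta, dtype=float)
    if sigma_tilde_sq <= 0:
        raise ValueError("sigma_tilde_sq must be positive")
    x = np.concatenate([theta, [edp]])
    if grad:
        mu, dmu = emulators.joint_mean_grad(x)
    else:
        mu = emulators.predict(x.reshape(1, -1))[0]
    if not np.all(np.isfinite(mu)):
        raise FloatingPointError("non-finite emulator prediction")
    r0 = y.y0 - mu[0]
    rs = y.y_tilde - mu[1:]
    ll = (-0.5 * np.log(noise.sigma0_sq) - r0 ** 2 / (2 * noise.sigma0_sq)
          - (N_SEGMENTS / 2) * np.log(sigma_tilde_sq)
          - float(np.sum(rs ** 2)) / (2 * sigma_tilde_sq))
    if not grad:
        return float(ll)
    dtheta = (r0 / noise.sigma0_sq) * dmu[0, :4] \
        + (rs / sigma_tilde_sq) @ dmu[1:, :4]
    dsig = (-N_SEGMENTS / (2 * sigma_tilde_sq)
            + float(np.sum(rs ** 2)) / (2 * sigma_tilde_sq ** 2))
    return float(ll), dtheta, float(dsig)


try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard dependency
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=False, fastmath=True)
def _posterior_kernel(z, Xt, inv_l2, asig, ymean, ystd, xmean, xstd,
                      yobs, sigma0_sq, la, lb, slo, shi, edp):
    """Fused log-posterior and gradient over the unconstrained 5-vector.

    Numerically identical to the numpy reference path (tested); exists
    because this is the innermost loop of NUTS.
    """
    N, D = Xt.shape
    K = inv_l2.shape[0]
    # transforms
    s = np.empty(5)
    for j in range(5):
        zj = z[j]
        s[j] = 1.0 / (1.0 + np.exp(-zj)) if zj >= 0 else \
            np.exp(zj) / (1.0 + np.exp(zj))
    rng_t = lb - la
    log_theta = np.empty(4)
    theta = np.empty(4)
    for j in range(4):
        log_theta[j] = la + rng_t * s[j]
        theta[j] = np.exp(log_theta[j])
    sigma = slo + (shi - slo) * s[4]
    sig2 = sigma * sigma

    x_t = np.empty(5)
    for j in range(4):
        x_t[j] = (log_theta[j] - xmean[j]) / xstd[j]
    x_t[4] = (edp - xmean[4]) / xstd[4]

    # emulator means and gradients (standardized-input space)
    mu = np.zeros(K)
    gt = np.zeros((K, D))
    diffs = np.empty((N, D))
    for n in range(N):
        for d in range(D):
            diffs[n, d] = Xt[n, d] - x_t[d]
    for k in range(K):
        l0, l1, l2, l3, l4 = inv_l2[k, 0], inv_l2[k, 1], inv_l2[k, 2], \
            inv_l2[k, 3], inv_l2[k, 4]
        m_acc = 0.0
        g0 = g1 = g2 = g3 = g4 = 0.0
        for n in range(N):
            d0, d1, d2_, d3, d4 = diffs[n, 0], diffs[n, 1], diffs[n, 2], \
                diffs[n, 3], diffs[n, 4]
            q = d0 * d0 * l0 + d1 * d1 * l1 + d2_ * d2_ * l2 \
                + d3 * d3 * l3 + d4 * d4 * l4
            a = asig[k, n] * np.exp(-0.5 * q)
            m_acc += a
            g0 += a * d0
            g1 += a * d1
            g2 += a * d2_
            g3 += a * d3
            g4 += a * d4
        mu[k] = m_acc
        gt[k, 0] = g0 * l0
        gt[k, 1] = g1 * l1
        gt[k, 2] = g2 * l2
        gt[k, 3] = g3 * l3
        gt[k, 4] = g4 * l4
    # de-standardize; chain to raw inputs (log-dims 0..3)
    f = np.empty(K)
    for k in range(K):
        f[k] = ymean[k] + ystd[k] * mu[k]
    # d f_k / d theta_j = ystd_k * gt[k, j] / (xstd_j * theta_j)
    r0 = yobs[0] - f[0]
    ll = -0.5 * np.log(sigma0_sq) - r0 * r0 / (2.0 * sigma0_sq)
    sse = 0.0
    for k in range(1, K):
        rk = yobs[k] - f[k]
        sse += rk * rk
    n_strain = K - 1
    ll += -(n_strain / 2.0) * np.log(sig2) - sse / (2.0 * sig2)

    dll_dtheta = np.zeros(4)
    for j in range(4):
        g0 = ystd[0] * gt[0, j] / (xstd[j] * theta[j])
        acc = (r0 / sigma0_sq) * g0
        for k in range(1, K):
            gk = ystd[k] * gt[k, j] / (xstd[j] * theta[j])
            acc += (yobs[k] - f[k]) / sig2 * gk
        dll_dtheta[j] = acc
    dll_dsig2 = -n_strain / (2.0 * sig2) + sse / (2.0 * sig2 * sig2)

    # log-Jacobian (uniform priors on theta and sigma) and chain rule to z
    lp = ll
    grad = np.empty(5)
    for j in range(4):
        ls = -np.log(1.0 + np.exp(-z[j])) if z[j] >= 0 else \
            z[j] - np.log(1.0 + np.exp(z[j]))
        l1ms = -np.log(1.0 + np.exp(z[j])) if z[j] < 0 else \
            -z[j] - np.log(1.0 + np.exp(-z[j]))
        lp += log_theta[j] + np.log(rng_t) + ls + l1ms
        sp = s[j] * (1.0 - s[j])
        grad[j] = dll_dtheta[j] * theta[j] * rng_t * sp \
            + rng_t * sp + (1.0 - 2.0 * s[j])
    ls4 = -np.log(1.0 + np.exp(-z[4])) if z[4] >= 0 else \
        z[4] - np.log(1.0 + np.exp(z[4]))
    l1ms4 = -np.log(1.0 + np.exp(z[4])) if z[4] < 0 else \
        -z[4] - np.log(1.0 + np.exp(-z[4]))
    lp += np.log(shi - slo) + ls4 + l1ms4
    sp4 = s[4] * (1.0 - s[4])
    grad[4] = dll_dsig2 * 2.0 * sigma * (shi - slo) * sp4 + (1.0 - 2.0 * s[4])
    return lp, grad


def make_log_posterior(y: ObservationVector, emulators: MultiOutputEmulator,
                       noise: NoiseModel, edp: float,
                       theta_bounds=DESIGN_BOUNDS["a"], use_numba=None):
    """Log posterior (and gradient) over the unconstrained 5-vector z.

    Uses the fused compiled kernel when numba is available (the numpy path
    remains as the tested reference implementation).
    """
    rep = _Reparam(theta_bounds, noise.sigma_tilde_bounds)
    if use_numba is None:
        use_numba = _HAVE_NUMBA
    if use_numba and not np.array_equal(
            emulators._ref.log_mask_, np.array([True] * 4 + [False])):
        use_numba = False  # kernel assumes the reduced input layout
    if use_numba:
        ref = emulators._ref
        Xt = np.ascontiguousarray(emulators._Xt)
        inv_l2 = np.ascontiguousarray(emulators._inv_l2)
        asig = np.ascontiguousarray(emulators._asig)
        ymean, ystd = emulators._ymean, emulators._ystd
        xmean, xstd = ref.x_mean_, ref.x_std_
        yobs = np.concatenate([[y.y0], y.y_tilde])
        args = (Xt, inv_l2, asig, ymean, ystd, xmean, xstd, yobs,
                noise.sigma0_sq, rep.la, rep.lb, rep.slo, rep.shi,
                float(edp))

        def logp_and_grad(z):
            return _posterior_kernel(np.asarray(z, dtype=float), *args)

        return logp_and_grad, rep

    def logp_and_grad(z):
        theta, sig2 = rep.forward(z)
        ll, dtheta, dsig2 = log_likelihood(y, theta, sig2, emulators, noise,
                                           edp, grad=True)
        lj, dlj = rep.log_jacobian_and_grad(z)
        s = _sigmoid(np.asarray(z, dtype=float))
        rng_t = rep.lb - rep.la
        # chain rule: dtheta/dz = theta * rng_t * s(1-s);
        # dsig2/dz = 2 sigma * (shi-slo) * s(1-s)
        g = np.empty(5)
        g[:4] = dtheta * theta * rng_t * s[:4] * (1 - s[:4])
        sigma = np.sqrt(sig2)
        g[4] = dsig2 * 2.0 * sigma * (rep.shi - rep.slo) * s[4] * (1 - s[4])
        return ll + lj, g + dlj

    return logp_and_grad, rep


def run_mcmc(y: ObservationVector, emulators: MultiOutputEmulator,
             edp: float, noise: NoiseModel | None = None,
             config: MCMCConfig | None = None):
    """Sample the reduced parameters with NUTS.

    Chains start from dispersed points (a Sobol sequence over the prior
    box).  Returns ``(PosteriorSamples, ConvergenceReport)``;
    non-convergence is flagged in the report, not fatal.
    """
    noise = noise or NoiseModel()
    config = config or MCMCConfig()
    logp, rep = make_log_posterior(y, emulators, noise, edp,
                                   config.theta_bounds)
    from .design import _sobol_points
    n_pow2 = 1 << (config.n_chains - 1).bit_length()
    sob = _sobol_points(5, n_pow2, config.seed)[:config.n_chains]
    # keep starts inside the open box but overdispersed
    u = 0.05 + 0.90 * sob
    lo, hi = config.theta_bounds
    slo, shi = noise.sigma_tilde_bounds
    all_draws = np.empty((config.n_chains, config.n_draws, 5))
    stats = []
    for c in range(config.n_chains):
        theta0 = np.exp(np.log(lo) + (np.log(hi) - np.log(lo)) * u[c, :4])
        sigma0 = slo + (shi - slo) * u[c, 4]
        z0 = rep.z_of(theta0, sigma0)
        rng = np.random.default_rng([config.seed, c])
        draws, st = nuts_chain(logp, z0, config.n_warmup, config.n_draws,
                               rng, max_treedepth=config.max_treedepth,
                               target_accept=config.target_accept)
        # map draws: z -> (log theta, log sigma2)
        s = _sigmoid(draws)
        all_draws[c, :, :4] = rep.la + (rep.lb - rep.la) * s[:, :4]
        sig = rep.slo + (rep.shi - rep.slo) * s[:, 4]
        all_draws[c, :, 4] = 2.0 * np.log(sig)
        stats.append(st)
    samples = PosteriorSamples(
        draws=all_draws, edp=float(edp),
        meta={"step_sizes": [s.step_size for s in stats],
              "mean_accept": [s.mean_accept for s in stats],
              "n_divergent": [s.n_divergent for s in stats],
              "seed": config.seed})
    report = samples.convergence(config.psrf_threshold)
    return samples, report


# -- diagnostics ------------------------------------------------------------

def psrf(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``chains`` is (m, n): m parallel chains of n draws of one scalar
    parameter.  With within-chain variance W and between-chain variance of
    means B/n, PSRF = sqrt(((n-1)/n W + B/n) / W).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 10:
        raise ValueError("need >= 2 chains of >= 10 draws")
    m, n = chains.shape
    W = float(np.mean(np.var(chains, axis=1, ddof=1)))
    if W <= 0.0:
        raise ValueError("zero within-chain variance; PSRF undefined")
    B_over_n = float(np.var(np.mean(chains, axis=1), ddof=1))
    v_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(v_hat / W))


def iiqr(samples) -> float:
    """Inverse interquartile range, 1/(q75 - q25).

    Large values mean a peaked marginal, i.e. good practical
    identifiability; a zero IQR (degenerate, point-mass posterior) raises.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 4:
        raise ValueError("need at least 4 samples")
    q25, q75 = np.percentile(samples, [25, 75])
    if q75 - q25 <= 0.0:
        raise ValueError("zero interquartile range; I-IQR undefined "
                         "(degenerate posterior)")
    return float(1.0 / (q75 - q25))


def run_iuq_battery(battery: list, emulators: MultiOutputEmulator,
                    noise: NoiseModel | None = None,
                    config: MCMCConfig | None = None,
                    edp_list=None, keep_samples: bool = False) -> pd.DataFrame:
    """Posterior inference for every battery case at every pressure.

    Returns a tidy frame with one row per (case, EDP, parameter):
    I-IQR and IQR of the natural-scale marginal, central 95% interval,
    the ground truth, the convergence flag, and the case's LVV-quartile
    bin (bins cut at the 0.25/0.5/0.75 quantiles of the battery's own
    noise-free volumes at EDP = 10 mmHg).  Failed runs are logged and
    excluded.
    """
    noise = noise or NoiseModel()
    config = config or MCMCConfig()
    lvv10 = {c["case_id"]: c["qois"][10.0].LVV for c in battery
             if 10.0 in c["qois"]}
    if lvv10:
        cuts = np.percentile(list(lvv10.values()), [25, 50, 75])
    rows = []
    samples_store = {}
    for case in battery:
        edps = edp_list if edp_list is not None else sorted(case["observations"])
        for edp in edps:
            if edp not in case["observations"]:
                continue
            y = ObservationVector.from_array(case["observations"][edp])
            cfg = MCMCConfig(**{**config.__dict__,
                                "seed": config.seed + 1000 * case["case_id"]
                                + int(10 * edp)})
            try:
                samples, report = run_mcmc(y, emulators, edp, noise, cfg)
            except Exception as err:  # pragma: no cover - defensive
                logger.warning("case %s EDP %s failed: %s",
                               case["case_id"], edp, err)
                continue
            if keep_samples:
                samples_store[(case["case_id"], edp)] = samples
            truth = case["params"].to_dict()
            lvv_bin = (int(np.searchsorted(cuts, lvv10[case["case_id"]]))
                       if case["case_id"] in lvv10 else -1)
            for name in REDUCED_NAMES:
                marg = samples.marginal(name)
                q = np.percentile(marg, [2.5, 25, 75, 97.5])
                rows.append({
                    "case_id": case["case_id"], "EDP": float(edp),
                    "param": name, "truth": truth[name],
                    "iiqr": 1.0 / (q[2] - q[1]), "iqr": q[2] - q[1],
                    "ci95_lo": q[0], "ci95_hi": q[3],
                    "covered": bool(q[0] <= truth[name] <= q[3]),
                    "max_psrf": report.max_psrf,
                    "converged": report.converged,
                    "lvv_bin": lvv_bin,
                })
    df = pd.DataFrame(rows)
    if keep_samples:
        df.attrs["samples"] = samples_store
    return df
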