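"""No-U-Turn sampler with dual-averaging step-size and diagonal mass
adaptation.

A self-contained implementation of multinomial NUTS (dynamic Hamiltonian
Monte Carlo with the no-U-turn termination criterion): trajectories are
doubled until the subtree ends make a U-turn in the metric induced by the
diagonal mass matrix, and the next state is drawn multinomially from the
trajectory with weights exp(-H).  Warmup adapts the step size to a target
acceptance statistic (dual averaging) and estimates the diagonal mass from
mid-warmup draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NUTSStats", "nuts_chain"]

_MAX_ENERGY_ERROR = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class NUTSStats:
    """Per-chain sampler diagnostics."""

    step_size: float
    mean_accept: float
    n_divergent: int
    tree_depths: np.ndarray = field(repr=False)


class _Tree:
    __slots__ = ("q_minus", "p_minus", "q_plus", "p_plus", "q_prop",
                 "log_weight", "sum_accept", "n_leap", "ok")

    def __init__(self, q_minus, p_minus, q_plus, p_plus, q_prop, log_weight,
                 sum_accept, n_leap, ok):
        self.q_minus, self.p_minus = q_minus, p_minus
        self.q_plus, self.p_plus = q_plus, p_plus
        self.q_prop = q_prop
        self.log_weight = log_weight
        self.sum_accept = sum_accept
        self.n_leap = n_leap
        self.ok = ok


def _logaddexp(a, b):
    return np.logaddexp(a, b)


def nuts_chain(logp_and_grad, q0, n_warmup: int, n_draws: int,
               rng: np.random.Generator, max_treedepth: int = 8,
               target_accept: float = 0.8, init_step: float | None = None):
    """Run one NUTS chain.

    ``logp_and_grad(q) -> (float, ndarray)`` is the log target density and
    its gradient.  Returns ``(draws (n_draws, d), NUTSStats)``; draws are
    post-warmup only.
    """
    q = np.asarray(q0, dtype=float).copy()
    d = q.size
    lp, grad = logp_and_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(d)

    def kinetic(p):
        return 0.5 * np.sum(inv_mass * p * p)

    def leapfrog(qc, pc, gradc, eps):
        p_half = pc + 0.5 * eps * gradc
        q_new = qc + eps * inv_mass * p_half
        lp_new, grad_new = logp_and_grad(q_new)
        p_new = p_half + 0.5 * eps * grad_new
        return q_new, p_new, lp_new, grad_new

    # -- step-size heuristic ------------------------------------------------
    eps = 1.0 if init_step is None else float(init_step)
    p0 = rng.standard_normal(d)
    H0 = lp - kinetic(p0)
    q1, p1, lp1, _ = leapfrog(q, p0, grad, eps)
    dH = (lp1 - kinetic(p1)) - H0 if np.isfinite(lp1) else -np.inf
    direction = 1.0 if dH > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        q1, p1, lp1, _ = leapfrog(q, p0, grad, eps)
        dH = (lp1 - kinetic(p1)) - H0 if np.isfinite(lp1) else -np.inf
        if (direction > 0) != (dH > np.log(0.5)):
            break

    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, H_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    # expanding mass-adaptation windows (Stan-style): an initial step-size
    # phase, then doubling covariance windows, then a terminal step-size
    # phase; the mass matrix is refreshed at each window end
    init_buffer = max(int(0.15 * n_warmup), 10)
    term_buffer = max(int(0.10 * n_warmup), 10)
    window_ends = []
    w = max(int(0.10 * n_warmup), 25)
    pos = init_buffer
    while pos + w < n_warmup - term_buffer:
        pos += w
        window_ends.append(pos)
        w *= 2
    if window_ends:
        window_ends[-1] = n_warmup - term_buffer
    mass_buf = []

    draws = np.empty((n_draws, d))
    depths = np.empty(n_warmup + n_draws, dtype=int)
    accept_probs = np.empty(n_warmup + n_draws)
    n_divergent = 0

    def u_turn(q_m, p_m, q_p, p_p):
        dq = q_p - q_m
        return (np.dot(dq, inv_mass * p_m) < 0.0
                or np.dot(dq, inv_mass * p_p) < 0.0)

    for it in range(n_warmup + n_draws):
        p = rng.standard_normal(d) / np.sqrt(inv_mass)
        H0 = lp - kinetic(p)

        def build(qc, pc, gradc, depth, direction, eps_it):
            nonlocal n_divergent
            if depth == 0:
                q_n, p_n, lp_n, grad_n = leapfrog(qc, pc, gradc,
                                                  direction * eps_it)
                H_n = lp_n - kinetic(p_n) if np.isfinite(lp_n) else -np.inf
                dH = H_n - H0
                if dH < -_MAX_ENERGY_ERROR:
                    # only count post-warmup divergences: early warmup
                    # explores unstable step sizes by design
                    if it >= n_warmup:
                        n_divergent += 1
                    return (_Tree(q_n, p_n, q_n, p_n, q_n, -np.inf, 0.0, 1,
                                  False), grad_n, lp_n)
                accept = min(1.0, float(np.exp(min(dH, 0.0))))
                return (_Tree(q_n, p_n, q_n, p_n, q_n, dH, accept, 1, True),
                        grad_n, lp_n)
            # inner then outer subtree
            t1, grad1, lp1_ = build(qc, pc, gradc, depth - 1, direction,
                                    eps_it)
            if not t1.ok:
                return t1, grad1, lp1_
            if direction > 0:
                t2, grad2, lp2_ = build(t1.q_plus, t1.p_plus, grad1,
                                        depth - 1, direction, eps_it)
                q_minus, p_minus = t1.q_minus, t1.p_minus
                q_plus, p_plus = t2.q_plus, t2.p_plus
            else:
                t2, grad2, lp2_ = build(t1.q_minus, t1.p_minus, grad1,
                                        depth - 1, direction, eps_it)
                q_minus, p_minus = t2.q_minus, t2.p_minus
                q_plus, p_plus = t1.q_plus, t1.p_plus
            log_w = _logaddexp(t1.log_weight, t2.log_weight)
            # multinomial choice between subtrees
            if np.log(rng.random()) < t2.log_weight - log_w:
                q_prop = t2.q_prop
            else:
                q_prop = t1.q_prop
            ok = t2.ok and not u_turn(q_minus, p_minus, q_plus, p_plus)
            tree = _Tree(q_minus, p_minus, q_plus, p_plus, q_prop, log_w,
                         t1.sum_accept + t2.sum_accept,
                         t1.n_leap + t2.n_leap, ok)
            return tree, grad2, lp2_

        # trajectory state: endpoints in both directions
        q_minus = q_plus = q
        p_minus = p_plus = p
        grad_minus = grad_plus = grad
        q_sel, lp_sel, grad_sel = q, lp, grad
        log_w_tot = 0.0  # weight of the initial point: exp(H - H0) = 1
        sum_accept, n_leap_tot = 0.0, 0
        depth = 0
        while depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction > 0:
                tree, grad_plus, _ = build(q_plus, p_plus, grad_plus, depth,
                                           1, eps)
                q_plus, p_plus = tree.q_plus, tree.p_plus
            else:
                tree, grad_minus, _ = build(q_minus, p_minus, grad_minus,
                                            depth, -1, eps)
                q_minus, p_minus = tree.q_minus, tree.p_minus
            sum_accept += tree.sum_accept
            n_leap_tot += tree.n_leap
            if not tree.ok:
                break
            # biased progressive sampling: prefer the new subtree
            if np.log(rng.random()) < tree.log_weight - log_w_tot:
                q_sel = tree.q_prop
            log_w_tot = _logaddexp(log_w_tot, tree.log_weight)
            if u_turn(q_minus, p_minus, q_plus, p_plus):
                depth += 1
                break
            depth += 1

        q = q_sel
        lp, grad = logp_and_grad(q)
        depths[it] = depth
        alpha = sum_accept / max(n_leap_tot, 1)
        accept_probs[it] = alpha

        if it < n_warmup:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            H_bar = (1 - frac) * H_bar + frac * (target_accept - alpha)
            log_eps = mu - np.sqrt(da_count) / gamma * H_bar
            w_da = da_count ** -kappa
            log_eps_bar = w_da * log_eps + (1 - w_da) * log_eps_bar
            eps = float(np.exp(log_eps))
            if it >= init_buffer:
                mass_buf.append(q.copy())
            if window_ends and it == window_ends[0] - 1 and len(mass_buf) >= 10:
                var = np.var(np.asarray(mass_buf), axis=0)
                n_b = len(mass_buf)
                # regularize towards unit metric (Stan-style shrinkage)
                inv_mass = (n_b / (n_b + 5.0)) * var + (5.0 / (n_b + 5.0)) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-8)
                mass_buf = []
                window_ends.pop(0)
                # restart step-size adaptation around the current value
                mu = np.log(10.0 * eps)
                H_bar, log_eps_bar, da_count = 0.0, np.log(eps), 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = q

    stats = NUTSStats(step_size=eps,
                      mean_accept=float(np.mean(accept_probs[n_warmup:]))
                      if n_draws else float("nan"),
                      n_divergent=n_divergent,
                      tree_depths=depths[n_warmup:])
    return draws, stats
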