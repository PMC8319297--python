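"""MCMC engines used by the model-fitting stages.

Three workhorses:

* :func:`nuts_sample` — a No-U-Turn sampler (slice variant, dual-averaging
  step-size adaptation, diagonal mass matrix) for models supplying a joint
  log density and its gradient on an unconstrained parameter vector.
* :func:`slice_sample` — univariate stepping-out slice sampling, used for
  scale hyperparameters inside Gibbs sweeps.
* :func:`sample_linear_model` — exact posterior draws for a Gaussian linear
  regression under the standard noninformative prior (used for the mediator
  model, where conjugacy makes MCMC unnecessary).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.random import Generator

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_MAX_DELTA_H = 1000.0  # divergence threshold on energy error


def slice_sample(logp: Callable[[float], float], x0: float, rng: Generator,
                 w: float = 1.0, max_steps: int = 50) -> float:
    """One update of univariate stepping-out slice sampling (Neal 2003)."""
    logy = logp(x0) + np.log(rng.uniform(1e-300, 1.0))
    u = rng.uniform(0.0, w)
    lo, hi = x0 - u, x0 - u + w
    j = int(np.floor(rng.uniform(0, max_steps)))
    k = max_steps - 1 - j
    while j > 0 and logp(lo) > logy:
        lo -= w
        j -= 1
    while k > 0 and logp(hi) > logy:
        hi += w
        k -= 1
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if logp(x1) > logy:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0  # shrunk to a point; keep current value


# ---------------------------------------------------------------------------
# NUTS
# ---------------------------------------------------------------------------

@dataclass
class _Tree:
    theta_minus: np.ndarray
    r_minus: np.ndarray
    grad_minus: np.ndarray
    theta_plus: np.ndarray
    r_plus: np.ndarray
    grad_plus: np.ndarray
    theta_prime: np.ndarray
    grad_prime: np.ndarray
    logp_prime: float
    n_prime: int
    s_prime: bool
    alpha: float
    n_alpha: int


def _leapfrog(theta, r, grad, eps, inv_mass, logp_grad):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_mass * r1
    logp1, grad1 = logp_grad(theta1)
    if not np.isfinite(logp1) or not np.all(np.isfinite(grad1)):
        # numerical overflow far in the tails: treat as zero density so the
        # trajectory is flagged divergent rather than silently accepted
        logp1 = -np.inf
        grad1 = np.zeros_like(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, logp1, grad1


def _stop_criterion(theta_minus, theta_plus, r_minus, r_plus, inv_mass):
    dtheta = theta_plus - theta_minus
    return (dtheta @ (inv_mass * r_minus) >= 0) and (dtheta @ (inv_mass * r_plus) >= 0)


class _NutsKernel:
    def __init__(self, logp_grad: LogpGrad, inv_mass: np.ndarray, max_depth: int):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.max_depth = max_depth
        self.divergent = False

    def _build_tree(self, theta, r, grad, logu, direction, depth, eps, joint0, rng):
        if depth == 0:
            theta1, r1, logp1, grad1 = _leapfrog(
                theta, r, grad, direction * eps, self.inv_mass, self.logp_grad
            )
            joint1 = logp1 - 0.5 * (r1 @ (self.inv_mass * r1))
            n1 = int(logu <= joint1)
            s1 = logu < joint1 + _MAX_DELTA_H
            if not s1:
                self.divergent = True
            de = joint1 - joint0
            alpha = float(np.exp(min(0.0, de))) if np.isfinite(de) else 0.0
            return _Tree(theta1, r1, grad1, theta1, r1, grad1, theta1, grad1,
                         logp1, n1, s1, alpha, 1)
        t = self._build_tree(theta, r, grad, logu, direction, depth - 1, eps, joint0, rng)
        if t.s_prime:
            if direction == -1:
                t2 = self._build_tree(t.theta_minus, t.r_minus, t.grad_minus, logu,
                                      direction, depth - 1, eps, joint0, rng)
                t.theta_minus, t.r_minus, t.grad_minus = (
                    t2.theta_minus, t2.r_minus, t2.grad_minus)
            else:
                t2 = self._build_tree(t.theta_plus, t.r_plus, t.grad_plus, logu,
                                      direction, depth - 1, eps, joint0, rng)
                t.theta_plus, t.r_plus, t.grad_plus = (
                    t2.theta_plus, t2.r_plus, t2.grad_plus)
            if t2.n_prime > 0 and rng.uniform() < t2.n_prime / max(t.n_prime + t2.n_prime, 1):
                t.theta_prime = t2.theta_prime
                t.grad_prime = t2.grad_prime
                t.logp_prime = t2.logp_prime
            t.n_prime += t2.n_prime
            t.s_prime = bool(
                t2.s_prime
                and _stop_criterion(t.theta_minus, t.theta_plus, t.r_minus, t.r_plus,
                                    self.inv_mass)
            )
            t.alpha += t2.alpha
            t.n_alpha += t2.n_alpha
        return t

    def step(self, theta, logp, grad, eps, rng):
        self.divergent = False
        mass = 1.0 / self.inv_mass
        r0 = rng.normal(size=theta.shape) * np.sqrt(mass)
        joint0 = logp - 0.5 * (r0 @ (self.inv_mass * r0))
        logu = joint0 + np.log(rng.uniform(1e-300, 1.0))
        theta_minus = theta_plus = theta
        r_minus = r_plus = r0
        grad_minus = grad_plus = grad
        theta_new, logp_new, grad_new = theta, logp, grad
        n, s, depth = 1, True, 0
        alpha_sum, n_alpha = 0.0, 0
        while s and depth < self.max_depth:
            direction = -1 if rng.uniform() < 0.5 else 1
            if direction == -1:
                t = self._build_tree(theta_minus, r_minus, grad_minus, logu,
                                     direction, depth, eps, joint0, rng)
                theta_minus, r_minus, grad_minus = t.theta_minus, t.r_minus, t.grad_minus
            else:
                t = self._build_tree(theta_plus, r_plus, grad_plus, logu,
                                     direction, depth, eps, joint0, rng)
                theta_plus, r_plus, grad_plus = t.theta_plus, t.r_plus, t.grad_plus
            if t.s_prime and t.n_prime > 0 and rng.uniform() < min(1.0, t.n_prime / n):
                theta_new, logp_new, grad_new = t.theta_prime, t.logp_prime, t.grad_prime
            n += t.n_prime
            s = bool(t.s_prime and _stop_criterion(theta_minus, theta_plus,
                                                   r_minus, r_plus, self.inv_mass))
            alpha_sum += t.alpha
            n_alpha += t.n_alpha
            depth += 1
        accept_stat = alpha_sum / max(n_alpha, 1)
        return theta_new, logp_new, grad_new, accept_stat, self.divergent


def _find_reasonable_epsilon(theta, logp, grad, inv_mass, logp_grad, rng):
    eps = 1.0
    mass = 1.0 / inv_mass
    r = rng.normal(size=theta.shape) * np.sqrt(mass)
    joint0 = logp - 0.5 * (r @ (inv_mass * r))
    _, r1, logp1, _ = _leapfrog(theta, r, grad, eps, inv_mass, logp_grad)
    joint1 = logp1 - 0.5 * (r1 @ (inv_mass * r1))
    if not np.isfinite(joint1):
        joint1 = -np.inf
    direction = 1.0 if joint1 - joint0 > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        _, r1, logp1, _ = _leapfrog(theta, r, grad, eps, inv_mass, logp_grad)
        joint1 = logp1 - 0.5 * (r1 @ (inv_mass * r1))
        if not np.isfinite(joint1):
            joint1 = -np.inf
        if direction * (joint1 - joint0) <= direction * np.log(0.5):
            break
    # cap: a huge step found from a flat tail region destabilizes the
    # subsequent dual-averaging window
    return float(np.clip(eps, 1e-8, 2.0))


def nuts_sample(
    logp_grad: LogpGrad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: Generator,
    target_accept: float = 0.85,
    max_depth: int = 8,
) -> tuple[np.ndarray, dict]:
    """Run one NUTS chain; returns (draws array (n_draws, dim), info)."""
    theta = np.asarray(x0, dtype=float).copy()
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("non-finite log density at the initial point")
    dim = theta.size
    inv_mass = np.ones(dim)
    kernel = _NutsKernel(logp_grad, inv_mass, max_depth)

    eps = _find_reasonable_epsilon(theta, logp, grad, inv_mass, logp_grad, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    # mass-adaptation window: middle portion of warmup; leave a generous
    # terminal window so the step size re-equilibrates after the metric change
    win_start = min(int(0.2 * n_warmup), 100)
    win_end = max(n_warmup - max(int(0.3 * n_warmup), 50), win_start + 1)
    acc = []
    divergences = 0
    m_adapt = 0

    draws = np.empty((n_draws, dim))
    total = n_warmup + n_draws
    for m in range(total):
        theta, logp, grad, a_stat, div = kernel.step(theta, logp, grad, eps, rng)
        if m < n_warmup:
            m_adapt += 1
            frac = 1.0 / (m_adapt + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - a_stat)
            log_eps = mu - np.sqrt(m_adapt) / gamma * h_bar
            eta = m_adapt ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if win_start <= m < win_end:
                acc.append(theta.copy())
            if m == win_end - 1 and len(acc) >= 10:
                var = np.var(np.asarray(acc), axis=0, ddof=1)
                n_acc = len(acc)
                # regularize toward unit metric (Stan-style)
                inv_mass = (n_acc / (n_acc + 5.0)) * var + (5.0 / (n_acc + 5.0)) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-10)
                kernel.inv_mass = inv_mass
                eps = _find_reasonable_epsilon(theta, logp, grad, inv_mass,
                                               logp_grad, rng)
                mu = np.log(10.0 * eps)
                h_bar, log_eps_bar, m_adapt = 0.0, 0.0, 0
            if m == n_warmup - 1:
                eps = float(np.exp(log_eps_bar)) if m_adapt > 0 else eps
        else:
            if div:
                divergences += 1
            draws[m - n_warmup] = theta
    info = {"step_size": eps, "divergences": divergences}
    return draws, info


def run_nuts_chains(
    logp_grad: LogpGrad,
    init: Callable[[Generator], np.ndarray],
    dim: int,
    chains: int,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.85,
    max_depth: int = 8,
) -> tuple[np.ndarray, dict]:
    """Run several NUTS chains; returns draws (chain, draw, dim) and info."""
    seqs = np.random.SeedSequence(seed).spawn(chains)
    out = np.empty((chains, n_draws, dim))
    divergences = 0
    step_sizes = []
    for c, seq in enumerate(seqs):
        rng = np.random.default_rng(seq)
        x0 = np.asarray(init(rng), dtype=float)
        if x0.size != dim:
            raise ValueError("init returned wrong dimension")
        out[c], info = nuts_sample(logp_grad, x0, n_warmup, n_draws, rng,
                                   target_accept=target_accept, max_depth=max_depth)
        divergences += info["divergences"]
        step_sizes.append(info["step_size"])
    return out, {"divergences": divergences, "step_sizes": step_sizes}


# ---------------------------------------------------------------------------
# Conjugate Gaussian linear regression
# ---------------------------------------------------------------------------

def sample_linear_model(
    X: np.ndarray,
    y: np.ndarray,
    chains: int,
    n_draws: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact posterior draws for y = X b + e, e ~ N(0, s^2).

    Under the reference prior p(b, s^2) ∝ 1/s^2 the posterior is
    normal–inverse-gamma: s^2 ~ SSR * Inv-Chi2(n-p), b | s^2 ~ N(bhat,
    s^2 (X'X)^-1). Returns (beta draws (chain, draw, p), sigma draws
    (chain, draw)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than parameters")
    xtx = X.T @ X
    try:
        L = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular design matrix") from err
    bhat = np.linalg.solve(xtx, X.T @ y)
    ssr = float((y - X @ bhat) @ (y - X @ bhat))
    nu = n - p
    rng = np.random.default_rng(seed)
    beta = np.empty((chains, n_draws, p))
    sigma = np.empty((chains, n_draws))
    lt_inv = np.linalg.inv(L).T  # (X'X)^-1 = Lt_inv @ Lt_inv.T
    for c in range(chains):
        s2 = ssr / rng.chisquare(nu, size=n_draws)
        z = rng.normal(size=(n_draws, p))
        beta[c] = bhat + np.sqrt(s2)[:, None] * (z @ lt_inv.T)
        sigma[c] = np.sqrt(s2)
    return beta, sigma
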