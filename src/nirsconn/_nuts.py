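"""No-U-Turn sampler with dual-averaging step-size adaptation.

A self-contained gradient-based MCMC kernel operating on an arbitrary
differentiable log-density.  Implements the dynamic-trajectory NUTS
recursion with a slice variable, a diagonal mass matrix estimated from
the middle of the warm-up phase, and Nesterov dual averaging of the
step size toward a target acceptance statistic.

The interface is a single function, :func:`sample`, returning draws for
one chain; chains are run independently by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["sample", "ChainResult"]

_DELTA_MAX = 1000.0  # divergence threshold on the joint log-density


@dataclass
class ChainResult:
    draws: np.ndarray        # (n_draws, dim)
    accept_prob: float       # mean acceptance statistic over kept draws
    n_divergent: int
    step_size: float


def _leapfrog(theta, r, grad, eps, inv_mass, logp_grad):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    logp, grad = logp_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, logp, grad


def _joint(logp, r, inv_mass):
    with np.errstate(over="ignore", invalid="ignore"):
        return logp - 0.5 * np.sum(inv_mass * r * r)


def _find_reasonable_epsilon(theta, logp, grad, inv_mass, logp_grad, rng):
    eps = 1.0
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = _joint(logp, r, inv_mass)
    _, r1, logp1, _ = _leapfrog(theta, r, grad, eps, inv_mass, logp_grad)
    h1 = _joint(logp1, r1, inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(theta, r, grad, eps, inv_mass, logp_grad)
        h1 = _joint(logp1, r1, inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return eps


class _Tree:
    """State shared across one NUTS trajectory."""

    __slots__ = ("logp_grad", "inv_mass", "rng", "log_u", "h0", "divergent",
                 "alpha_sum", "n_alpha")

    def __init__(self, logp_grad, inv_mass, rng, log_u, h0):
        self.logp_grad = logp_grad
        self.inv_mass = inv_mass
        self.rng = rng
        self.log_u = log_u
        self.h0 = h0
        self.divergent = False
        self.alpha_sum = 0.0
        self.n_alpha = 0

    def build(self, theta, r, grad, eps, v, depth):
        if depth == 0:
            theta1, r1, logp1, grad1 = _leapfrog(
                theta, r, grad, v * eps, self.inv_mass, self.logp_grad
            )
            h1 = _joint(logp1, r1, self.inv_mass)
            if not np.isfinite(h1):
                h1 = -np.inf
            n1 = int(self.log_u <= h1)
            s1 = int(self.log_u < h1 + _DELTA_MAX)
            if not s1:
                self.divergent = True
            self.alpha_sum += 1.0 if h1 >= self.h0 else np.exp(h1 - self.h0)
            self.n_alpha += 1
            return theta1, r1, grad1, theta1, r1, grad1, theta1, logp1, grad1, n1, s1
        (tm, rm, gm, tp, rp, gp, tprop, lprop, gprop, n1, s1) = self.build(
            theta, r, grad, eps, v, depth - 1
        )
        if s1:
            if v == -1:
                tm, rm, gm, _, _, _, tprop2, lprop2, gprop2, n2, s2 = self.build(
                    tm, rm, gm, eps, v, depth - 1
                )
            else:
                _, _, _, tp, rp, gp, tprop2, lprop2, gprop2, n2, s2 = self.build(
                    tp, rp, gp, eps, v, depth - 1
                )
            if n2 > 0 and self.rng.random() < n2 / max(n1 + n2, 1):
                tprop, lprop, gprop = tprop2, lprop2, gprop2
            dt = tp - tm
            s1 = s2 * int(dt @ (self.inv_mass * rm) >= 0) * int(dt @ (self.inv_mass * rp) >= 0)
            n1 = n1 + n2
        return tm, rm, gm, tp, rp, gp, tprop, lprop, gprop, n1, s1


def _window_ends(n_warmup: int) -> list[int]:
    """Stan-style expanding adaptation windows for the mass matrix.

    An initial fast phase (step size only), then doubling slow windows
    whose ends trigger a mass-matrix re-estimate, then a terminal fast
    phase.
    """
    init = max(10, int(0.15 * n_warmup))
    term = max(10, int(0.10 * n_warmup))
    ends = []
    start, width = init, max(25, int(0.1 * n_warmup))
    while start + width < n_warmup - term:
        nxt = start + width
        # absorb a final too-small window into the previous one
        if nxt + 2 * width >= n_warmup - term:
            nxt = n_warmup - term
        ends.append(nxt)
        start, width = nxt, 2 * width
    if not ends and n_warmup > init + term + 10:
        ends.append(n_warmup - term)
    return ends


def sample(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.95,
    max_depth: int = 10,
) -> ChainResult:
    """Run one NUTS chain and return post-warm-up draws.

    ``logp_grad`` must return the log-density and its gradient.  The
    diagonal mass matrix is re-estimated at the end of each expanding
    warm-up window; step-size dual averaging restarts after every
    re-estimate.
    """
    theta = np.array(x0, dtype=float)
    dim = theta.size
    logp, grad = logp_grad(theta)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log-density")
    inv_mass = np.ones(dim)

    eps = _find_reasonable_epsilon(theta, logp, grad, inv_mass, logp_grad, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    win_ends = _window_ends(n_warmup)
    win_start = max(10, int(0.15 * n_warmup)) if win_ends else n_warmup
    acc_sum = np.zeros(dim)
    acc_sq = np.zeros(dim)
    acc_n = 0

    draws = np.empty((n_draws, dim))
    n_divergent = 0
    accept_sum = 0.0
    adapt_iter = 0

    for it in range(n_warmup + n_draws):
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = _joint(logp, r0, inv_mass)
        log_u = h0 - rng.exponential()
        tree = _Tree(logp_grad, inv_mass, rng, log_u, h0)
        tm = tp = theta
        rm = rp = r0
        gm = gp = grad
        n_kept, s = 1, 1
        for depth in range(max_depth):
            v = -1 if rng.random() < 0.5 else 1
            if v == -1:
                tm, rm, gm, _, _, _, tprop, lprop, gprop, n1, s1 = tree.build(
                    tm, rm, gm, eps, v, depth
                )
            else:
                _, _, _, tp, rp, gp, tprop, lprop, gprop, n1, s1 = tree.build(
                    tp, rp, gp, eps, v, depth
                )
            if s1 and rng.random() < min(1.0, n1 / n_kept):
                theta, logp, grad = tprop, lprop, gprop
            n_kept += n1
            dt = tp - tm
            s = s1 * int(dt @ (inv_mass * rm) >= 0) * int(dt @ (inv_mass * rp) >= 0)
            if not s:
                break

        alpha = tree.alpha_sum / max(tree.n_alpha, 1)
        if it < n_warmup:
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (target_accept - alpha)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * h_bar
            w = adapt_iter ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if it >= win_start:
                acc_sum += theta
                acc_sq += theta * theta
                acc_n += 1
            if win_ends and it == win_ends[0] - 1 and acc_n >= 10:
                var = acc_sq / acc_n - (acc_sum / acc_n) ** 2
                # Stan-style regularization toward unit scale
                var = (acc_n / (acc_n + 5.0)) * var + (5.0 / (acc_n + 5.0)) * 1e-3
                inv_mass = np.maximum(var, 1e-10)
                acc_sum[:] = 0.0
                acc_sq[:] = 0.0
                acc_n = 0
                win_ends.pop(0)
                eps = _find_reasonable_epsilon(theta, logp, grad, inv_mass, logp_grad, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_iter = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            draws[it - n_warmup] = theta
            accept_sum += alpha
            if tree.divergent:
                n_divergent += 1

    return ChainResult(
        draws=draws,
        accept_prob=accept_sum / max(n_draws, 1),
        n_divergent=n_divergent,
        step_size=float(eps),
    )
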