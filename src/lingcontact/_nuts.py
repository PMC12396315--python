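"""No-U-Turn sampler with dual-averaging step size and diagonal mass adaptation.

A self-contained implementation of multinomial NUTS operating on an
unconstrained parameter vector, given a callable returning the log target
density and its gradient.  Warmup follows the usual windowed scheme: an
initial fast interval adapting only the step size, doubling slow windows
re-estimating the diagonal inverse mass from the warmup draws, and a final
fast interval.  Trajectories exceeding an energy error of 1000 are counted
as divergent.  All randomness flows through a numpy Generator, so runs are
reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]

_MAX_ENERGY_ERROR = 1000.0


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_draws, dim)
    n_divergent: int
    accept_rate: float
    step_size: float
    treedepths: np.ndarray


class _Tree:
    __slots__ = (
        "theta_minus", "r_minus", "grad_minus",
        "theta_plus", "r_plus", "grad_plus",
        "theta_prop", "logp_prop", "grad_prop",
        "log_sum_w", "sum_accept", "n_leaves", "n_div", "turning",
    )


def _leapfrog(logp_grad: LogpGrad, theta, r, grad, eps, inv_mass):
    r = r + 0.5 * eps * grad
    theta = theta + eps * inv_mass * r
    logp, grad = logp_grad(theta)
    r = r + 0.5 * eps * grad
    return theta, r, logp, grad


def _kinetic(r: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(r, inv_mass * r))


def _is_turning(theta_minus, theta_plus, r_minus, r_plus, inv_mass) -> bool:
    dtheta = theta_plus - theta_minus
    return (
        float(np.dot(dtheta, inv_mass * r_minus)) < 0
        or float(np.dot(dtheta, inv_mass * r_plus)) < 0
    )


def _build_tree(
    logp_grad, theta, r, grad, v, depth, eps, inv_mass, logh0, rng
) -> _Tree:
    t = _Tree()
    if depth == 0:
        theta1, r1, logp1, grad1 = _leapfrog(logp_grad, theta, r, grad, v * eps, inv_mass)
        logh = logp1 - _kinetic(r1, inv_mass)
        energy_err = logh - logh0
        divergent = (not math.isfinite(logh)) or (energy_err < -_MAX_ENERGY_ERROR)
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.r_minus = t.r_plus = r1
        t.grad_minus = t.grad_plus = t.grad_prop = grad1
        t.logp_prop = logp1
        t.log_sum_w = -np.inf if divergent else energy_err
        t.sum_accept = math.exp(min(0.0, energy_err)) if math.isfinite(energy_err) else 0.0
        t.n_leaves = 1
        t.n_div = int(divergent)
        t.turning = divergent
        return t

    first = _build_tree(logp_grad, theta, r, grad, v, depth - 1, eps, inv_mass, logh0, rng)
    if first.turning:
        return first
    if v == 1:
        second = _build_tree(
            logp_grad, first.theta_plus, first.r_plus, first.grad_plus,
            v, depth - 1, eps, inv_mass, logh0, rng,
        )
        first.theta_plus, first.r_plus, first.grad_plus = (
            second.theta_plus, second.r_plus, second.grad_plus,
        )
    else:
        second = _build_tree(
            logp_grad, first.theta_minus, first.r_minus, first.grad_minus,
            v, depth - 1, eps, inv_mass, logh0, rng,
        )
        first.theta_minus, first.r_minus, first.grad_minus = (
            second.theta_minus, second.r_minus, second.grad_minus,
        )
    total = np.logaddexp(first.log_sum_w, second.log_sum_w)
    if math.isfinite(second.log_sum_w) and math.log(rng.random() + 1e-300) < second.log_sum_w - total:
        first.theta_prop = second.theta_prop
        first.logp_prop = second.logp_prop
        first.grad_prop = second.grad_prop
    first.log_sum_w = total
    first.sum_accept += second.sum_accept
    first.n_leaves += second.n_leaves
    first.n_div += second.n_div
    first.turning = (
        second.turning
        or _is_turning(first.theta_minus, first.theta_plus, first.r_minus, first.r_plus, inv_mass)
    )
    return first


def _find_reasonable_epsilon(logp_grad, theta, grad, logp, inv_mass, rng) -> float:
    eps = 0.1
    r = rng.standard_normal(theta.shape) / np.sqrt(inv_mass)
    logh0 = logp - _kinetic(r, inv_mass)
    _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
    logh1 = logp1 - _kinetic(r1, inv_mass)
    if not math.isfinite(logh1):
        logh1 = -np.inf
    direction = 1.0 if (logh1 - logh0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, eps, inv_mass)
        logh1 = logp1 - _kinetic(r1, inv_mass)
        if not math.isfinite(logh1):
            logh1 = -np.inf
        if direction * (logh1 - logh0) <= direction * math.log(0.5):
            break
    return float(eps)


def _adaptation_schedule(n_warmup: int) -> list[tuple[int, int, bool]]:
    """(start, end, is_slow_window) intervals in the Stan style."""
    if n_warmup < 60:
        return [(0, n_warmup, False)]
    init = 75 if n_warmup >= 150 else max(10, n_warmup // 10)
    term = 50 if n_warmup >= 150 else max(10, n_warmup // 10)
    slow_total = n_warmup - init - term
    windows = []
    start = init
    size = 25 if n_warmup >= 150 else max(5, slow_total // 4)
    while slow_total > 0:
        if slow_total < 2 * size:
            size = slow_total
        windows.append((start, start + size, True))
        start += size
        slow_total -= size
        size *= 2
    return [(0, init, False)] + windows + [(n_warmup - term, n_warmup, False)]


def nuts(
    logp_grad: LogpGrad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws and sampler statistics."""
    theta = np.array(theta0, dtype=float)
    dim = theta.size
    inv_mass = np.ones(dim)
    logp, grad = logp_grad(theta)
    if not math.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_epsilon(logp_grad, theta, grad, logp, inv_mass, rng)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    schedule = _adaptation_schedule(n_warmup)
    slow_ends = {end for (start, end, slow) in schedule if slow}
    window_buf: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    treedepths = np.empty(n_draws, dtype=int)
    n_divergent = 0
    accept_sum = 0.0

    for it in range(n_warmup + n_draws):
        warming = it < n_warmup
        if it == n_warmup and n_warmup > 0:
            eps = math.exp(log_eps_bar)
        r0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        logh0 = logp - _kinetic(r0, inv_mass)
        theta_minus = theta_plus = theta
        r_minus = r_plus = r0
        grad_minus = grad_plus = grad
        theta_prop, logp_prop, grad_prop = theta, logp, grad
        log_sum_w = 0.0
        sum_accept, n_leaves = 0.0, 0
        depth = 0
        divergences_here = 0
        while depth < max_treedepth:
            v = 1 if rng.random() < 0.5 else -1
            if v == 1:
                sub = _build_tree(
                    logp_grad, theta_plus, r_plus, grad_plus, 1, depth, eps, inv_mass, logh0, rng
                )
                theta_plus, r_plus, grad_plus = sub.theta_plus, sub.r_plus, sub.grad_plus
            else:
                sub = _build_tree(
                    logp_grad, theta_minus, r_minus, grad_minus, -1, depth, eps, inv_mass, logh0, rng
                )
                theta_minus, r_minus, grad_minus = sub.theta_minus, sub.r_minus, sub.grad_minus
            sum_accept += sub.sum_accept
            n_leaves += sub.n_leaves
            divergences_here += sub.n_div
            if sub.turning:
                break
            if math.isfinite(sub.log_sum_w) and math.log(rng.random() + 1e-300) < sub.log_sum_w - log_sum_w:
                theta_prop, logp_prop, grad_prop = sub.theta_prop, sub.logp_prop, sub.grad_prop
            log_sum_w = float(np.logaddexp(log_sum_w, sub.log_sum_w))
            depth += 1
            if _is_turning(theta_minus, theta_plus, r_minus, r_plus, inv_mass):
                break
        theta, logp, grad = theta_prop, logp_prop, grad_prop
        accept_stat = sum_accept / max(n_leaves, 1)

        if warming:
            adapt_count += 1
            h_bar = (1.0 - 1.0 / (adapt_count + t0)) * h_bar + (
                (target_accept - accept_stat) / (adapt_count + t0)
            )
            log_eps = mu - math.sqrt(adapt_count) / gamma * h_bar
            w = adapt_count ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = math.exp(log_eps)

            in_slow = any(start <= it < end for (start, end, slow) in schedule if slow)
            if in_slow:
                window_buf.append(theta.copy())
            if (it + 1) in slow_ends and len(window_buf) >= 10:
                sample = np.asarray(window_buf)
                n = sample.shape[0]
                var = sample.var(axis=0, ddof=1)
                inv_mass = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                window_buf = []
                eps = _find_reasonable_epsilon(logp_grad, theta, grad, logp, inv_mass, rng)
                mu = math.log(10.0 * eps)
                log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
        else:
            idx = it - n_warmup
            draws[idx] = theta
            treedepths[idx] = depth
            n_divergent += divergences_here
            accept_sum += accept_stat

    return NutsResult(
        draws=draws,
        n_divergent=n_divergent,
        accept_rate=accept_sum / max(n_draws, 1),
        step_size=eps,
        treedepths=treedepths,
    )
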