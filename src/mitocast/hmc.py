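"""Adaptive Hamiltonian Monte Carlo on an unconstrained parameter space.

A single-trajectory HMC sampler with dual-averaging step-size adaptation
(Hoffman & Gelman 2014 scheme), diagonal mass-matrix estimation from the
middle of warmup, jittered leapfrog trajectory lengths (guards against
resonant periodic trajectories), and Stan-style divergence detection (an
energy error above a large threshold, or a non-finite density, marks the
transition as divergent and rejects it).

The target is supplied as ``logp_grad(theta) -> (float, ndarray)``; all
gradients are analytic in this package, so each leapfrog step costs one
cheap closed-form evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ChainResult", "sample_chain"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class ChainResult:
    """Post-warmup output of one chain."""

    draws: np.ndarray  # (n_draws, dim), unconstrained coordinates
    energy: np.ndarray  # (n_draws,) Hamiltonian at each iteration start
    divergent: np.ndarray  # (n_draws,) bool
    accept_prob: np.ndarray  # (n_draws,) Metropolis acceptance statistic
    step_size: float
    inv_mass: np.ndarray
    n_divergent_warmup: int


def _leapfrog(logp_grad, x, p, grad, eps, n_steps, inv_mass):
    """Integrate Hamilton's equations; returns None on numerical blow-up."""
    p = p + 0.5 * eps * grad
    for step in range(n_steps):
        x = x + eps * p * inv_mass
        logp, grad = logp_grad(x)
        if not math.isfinite(logp):
            return None
        if step < n_steps - 1:
            p = p + eps * grad
    p = p + 0.5 * eps * grad
    return x, p, logp, grad


def _kinetic(p, inv_mass):
    with np.errstate(over="ignore"):
        return 0.5 * float(np.dot(p * p, inv_mass))


def _find_reasonable_step_size(logp_grad, x, logp, grad, inv_mass, rng):
    """Stan's heuristic: scale eps until one leapfrog step crosses 50% accept."""
    eps = 0.1
    sqrt_mass = 1.0 / np.sqrt(inv_mass)
    p = rng.standard_normal(x.size) * sqrt_mass
    h0 = -logp + _kinetic(p, inv_mass)

    def accept_log_ratio(eps):
        out = _leapfrog(logp_grad, x, p, grad, eps, 1, inv_mass)
        if out is None:
            return -np.inf
        _, p1, logp1, _ = out
        return h0 - (-logp1 + _kinetic(p1, inv_mass))

    ratio = accept_log_ratio(eps)
    direction = 1.0 if ratio > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        ratio = accept_log_ratio(eps)
        if direction > 0 and ratio <= math.log(0.5):
            break
        if direction < 0 and ratio >= math.log(0.5):
            break
        if eps < 1e-10 or eps > 1e6:
            break
    return max(min(eps, 1e3), 1e-8)


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, eps0: float, target: float, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.t = 0
        self.h_bar = 0.0
        self.log_eps_bar = math.log(eps0)
        self.log_eps = math.log(eps0)

    def update(self, accept_stat: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(self.t) / self.gamma * self.h_bar
        weight = self.t ** (-self.kappa)
        self.log_eps_bar = weight * self.log_eps + (1 - weight) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


def sample_chain(
    logp_grad,
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_leapfrog: int = 48,
    divergence_threshold: float = _DIVERGENCE_THRESHOLD,
) -> ChainResult:
    """Run one HMC chain and return its post-warmup draws.

    Warmup schedule: step-size adaptation throughout; positions collected
    over the middle window (25%–75% of warmup) feed a diagonal mass-matrix
    estimate, after which step-size adaptation restarts against the new
    metric.  Deterministic given ``rng``'s state.
    """
    dim = x0.size
    x = np.asarray(x0, dtype=float).copy()
    logp, grad = logp_grad(x)
    if not math.isfinite(logp):
        raise ValueError("initial position has non-finite density")
    inv_mass = np.ones(dim)
    eps = _find_reasonable_step_size(logp_grad, x, logp, grad, inv_mass, rng)
    averager = _DualAveraging(eps, target_accept)

    mass_window_start = int(0.25 * n_warmup)
    mass_window_end = int(0.75 * n_warmup)
    window_positions: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    energy = np.empty(n_draws)
    divergent = np.zeros(n_draws, dtype=bool)
    accept_probs = np.empty(n_draws)
    n_div_warmup = 0

    total = n_warmup + n_draws
    sqrt_mass = 1.0 / np.sqrt(inv_mass)
    for it in range(total):
        warming = it < n_warmup
        p = rng.standard_normal(dim) * sqrt_mass
        h0 = -logp + _kinetic(p, inv_mass)
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        out = _leapfrog(logp_grad, x, p, grad, eps, n_steps, inv_mass)
        if out is None:
            is_div, accept_stat, delta_h = True, 0.0, np.inf
        else:
            x1, p1, logp1, grad1 = out
            h1 = -logp1 + _kinetic(p1, inv_mass)
            delta_h = h1 - h0
            is_div = not math.isfinite(delta_h) or delta_h > divergence_threshold
            if is_div:
                accept_stat = 0.0
            else:
                accept_stat = 1.0 if delta_h <= 0 else math.exp(-delta_h)
        if not is_div and math.log(rng.random() + 1e-300) < -delta_h:
            x, logp, grad = x1, logp1, grad1

        if warming:
            n_div_warmup += int(is_div)
            eps = averager.update(accept_stat)
            if mass_window_start <= it < mass_window_end:
                window_positions.append(x.copy())
            if it == mass_window_end - 1 and len(window_positions) >= 10:
                pos = np.asarray(window_positions)
                var = pos.var(axis=0)
                w = pos.shape[0]
                # Stan-style regularization toward unit metric
                inv_mass = (w / (w + 5.0)) * var + 1e-3 * (5.0 / (w + 5.0))
                inv_mass = np.maximum(inv_mass, 1e-8)
                sqrt_mass = 1.0 / np.sqrt(inv_mass)
                eps = _find_reasonable_step_size(
                    logp_grad, x, logp, grad, inv_mass, rng
                )
                averager = _DualAveraging(eps, target_accept)
            if it == n_warmup - 1:
                eps = averager.adapted
        else:
            i = it - n_warmup
            draws[i] = x
            energy[i] = h0
            divergent[i] = is_div
            accept_probs[i] = accept_stat

    return ChainResult(
        draws=draws,
        energy=energy,
        divergent=divergent,
        accept_prob=accept_probs,
        step_size=eps,
        inv_mass=inv_mass,
        n_divergent_warmup=n_div_warmup,
    )
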