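"""Adaptive Hamiltonian Monte Carlo with vectorized chains.

A compact HMC implementation (leapfrog integrator, dual-averaging step-size
adaptation, windowed diagonal mass-matrix adaptation, jittered trajectory
lengths) sufficient for the moderate-dimensional hierarchical posteriors in
:mod:`deerlcu.validation`.  All chains advance in lock-step through shared
numpy batches; each chain keeps its own step size and mass matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

LogpGrad = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class HMCDraws:
    """Posterior draws with sampler telemetry."""

    draws: np.ndarray  # (chains, n_draws, dim)
    accept_rate: np.ndarray  # (chains,)
    step_size: np.ndarray  # (chains,)
    divergences: int


class _DualAveraging:
    """Nesterov dual averaging toward a target acceptance rate (one state
    per chain)."""

    def __init__(self, eps0: np.ndarray, target: float) -> None:
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.log_eps = np.log(eps0)
        self.log_eps_bar = np.log(eps0)
        self.h_bar = np.zeros_like(eps0)
        self.m = 0
        self.gamma = 0.05
        self.t0 = 10.0
        self.kappa = 0.75

    def update(self, accept_prob: np.ndarray) -> None:
        self.m += 1
        w = 1.0 / (self.m + self.t0)
        self.h_bar = (1 - w) * self.h_bar + w * (self.target - accept_prob)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        eta = self.m ** (-self.kappa)
        self.log_eps_bar = eta * self.log_eps + (1 - eta) * self.log_eps_bar

    @property
    def eps(self) -> np.ndarray:
        return np.exp(self.log_eps)

    @property
    def eps_final(self) -> np.ndarray:
        return np.exp(self.log_eps_bar)


def sample_hmc(
    logp_grad: LogpGrad,
    init: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.85,
    max_leapfrog: int = 96,
    trajectory_length: float = 3.0,
    thin: int = 1,
) -> HMCDraws:
    """Run vectorized-chain HMC.

    Parameters
    ----------
    logp_grad
        Maps a ``(chains, dim)`` position batch to ``(logp, grad)`` with
        shapes ``(chains,)`` and ``(chains, dim)``.  Non-finite logp marks
        an invalid state (proposal rejected).
    init
        ``(chains, dim)`` initial positions.
    """
    theta = np.array(init, dtype=float)
    n_chains, dim = theta.shape
    inv_mass = np.ones_like(theta)
    eps0 = np.full(n_chains, 0.25 / dim**0.25)
    da = _DualAveraging(eps0, target_accept)

    lp, grad = logp_grad(theta)

    # mass-adaptation window inside warmup
    w_start, w_end = int(0.25 * n_warmup), int(0.8 * n_warmup)
    welford_n = 0
    welford_mean = np.zeros_like(theta)
    welford_m2 = np.zeros_like(theta)

    kept = np.empty((n_chains, n_draws, dim))
    n_accept = np.zeros(n_chains)
    divergences = 0
    eps = da.eps
    total_iters = n_warmup + n_draws * thin
    n_kept = 0

    for it in range(total_iters):
        in_warmup = it < n_warmup
        mean_eps = float(np.mean(eps))
        n_steps_cap = int(np.clip(round(trajectory_length / max(mean_eps, 1e-8)), 1, max_leapfrog))
        # jitter trajectory length a little to avoid resonances
        n_steps_lo = max(1, int(0.8 * n_steps_cap))
        n_steps = int(rng.integers(n_steps_lo, n_steps_cap + 1))

        # momentum ~ N(0, M); kinetic = p' M^{-1} p / 2
        p0 = rng.standard_normal(theta.shape) / np.sqrt(inv_mass)
        ke0 = 0.5 * np.sum(p0**2 * inv_mass, axis=1)
        h0 = lp - ke0

        q = theta.copy()
        p = p0.copy()
        g = grad.copy()
        e = eps[:, None]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            p = p + 0.5 * e * g
            for _ in range(n_steps):
                q = q + e * inv_mass * p
                lp_new, g = logp_grad(q)
                p = p + e * g
            p = p - 0.5 * e * g
        with np.errstate(over="ignore", invalid="ignore"):
            ke1 = 0.5 * np.sum(p**2 * inv_mass, axis=1)
            log_ratio = (lp_new - ke1) - h0
        log_ratio = np.where(np.isfinite(log_ratio), log_ratio, -np.inf)
        if not in_warmup:
            divergences += int(np.sum((log_ratio < -1000) & ~np.isneginf(h0)))

        accept_prob = np.exp(np.minimum(0.0, log_ratio))
        accept = np.log(rng.uniform(size=n_chains)) < log_ratio
        theta[accept] = q[accept]
        lp = np.where(accept, lp_new, lp)
        grad[accept] = g[accept]

        if in_warmup:
            da.update(accept_prob)
            eps = da.eps
            if w_start <= it < w_end:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
            if it == w_end - 1 and welford_n > 2:
                var = welford_m2 / (welford_n - 1)
                inv_mass = var + 1e-5
                # restart step-size adaptation around the current value
                da = _DualAveraging(np.maximum(da.eps_final, 1e-6), target_accept)
                eps = da.eps
            if it == n_warmup - 1:
                eps = da.eps_final
        else:
            n_accept += accept
            if (it - n_warmup) % thin == thin - 1:
                kept[:, n_kept] = theta
                n_kept += 1

    return HMCDraws(
        draws=kept,
        accept_rate=n_accept / (n_draws * thin),
        step_size=eps,
        divergences=divergences,
    )
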