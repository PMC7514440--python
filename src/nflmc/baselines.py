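"""Gradient-informed MCMC baselines: MALA and HMC.

Both samplers consume a :class:`~nflmc.targets.TargetDistribution` and share
the chain-configuration object, so diagnostics and file formats are
method-agnostic.  MALA proposes one Euler–Maruyama Langevin step

    x' = x - (eps^2/2) * grad U(x) + eps * z,    z ~ N(0, I)

and corrects with the Metropolis–Hastings ratio for the asymmetric Gaussian
proposal.  HMC integrates Hamiltonian dynamics with a unit mass matrix by
leapfrog, drawing the number of leapfrog steps uniformly from a configured
range each iteration and accepting on the total-energy change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .targets import TargetDistribution

__all__ = ["ChainConfig", "mala_chain", "hmc_chain", "leapfrog"]


@dataclass
class ChainConfig:
    step_size: float = 0.05
    n_iterations: int = 10000
    burn_in: int = 1000
    leapfrog_steps: Tuple[int, int] = (8, 12)   # inclusive range for HMC
    init_position: np.ndarray = None
    seed: int = 0

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        lo, hi = self.leapfrog_steps
        if not 1 <= lo <= hi:
            raise ValueError("invalid leapfrog step range")

    def start(self, dim):
        if self.init_position is None:
            return np.zeros(dim)
        x0 = np.asarray(self.init_position, dtype=float)
        if x0.shape != (dim,):
            raise ValueError(f"init_position must have shape ({dim},)")
        return x0


def mala_chain(target: TargetDistribution, config: ChainConfig):
    """Metropolis-adjusted Langevin chain; returns (samples, acceptance rate)."""
    rng = np.random.default_rng(config.seed)
    eps = config.step_size
    half = 0.5 * eps**2
    x = config.start(target.dim)
    u = target.energy(x)
    g = target.grad_energy(x)
    out = np.empty((config.n_iterations - config.burn_in, target.dim))
    accepted = 0
    for it in range(config.n_iterations):
        mean_fwd = x - half * g
        prop = mean_fwd + eps * rng.standard_normal(target.dim)
        u_prop = target.energy(prop)
        g_prop = target.grad_energy(prop)
        mean_rev = prop - half * g_prop
        # ln q(x | x') - ln q(x' | x) with isotropic eps^2 covariance
        log_q_rev = -np.sum((x - mean_rev) ** 2) / (2 * eps**2)
        log_q_fwd = -np.sum((prop - mean_fwd) ** 2) / (2 * eps**2)
        log_alpha = (u - u_prop) + (log_q_rev - log_q_fwd)
        if np.log(rng.uniform()) < log_alpha:
            x, u, g = prop, u_prop, g_prop
            accepted += 1
        if it >= config.burn_in:
            out[it - config.burn_in] = x
    return out, accepted / config.n_iterations


def leapfrog(target: TargetDistribution, x, p, eps, n_steps):
    """Leapfrog integration of (x, p) under H = U(x) + p.p/2."""
    x = x.copy()
    p = p - 0.5 * eps * target.grad_energy(x)
    for _ in range(n_steps - 1):
        x = x + eps * p
        p = p - eps * target.grad_energy(x)
    x = x + eps * p
    p = p - 0.5 * eps * target.grad_energy(x)
    return x, p


def hmc_chain(target: TargetDistribution, config: ChainConfig):
    """Hamiltonian Monte Carlo chain; returns (samples, acceptance rate)."""
    rng = np.random.default_rng(config.seed)
    eps = config.step_size
    lo, hi = config.leapfrog_steps
    x = config.start(target.dim)
    u = target.energy(x)
    out = np.empty((config.n_iterations - config.burn_in, target.dim))
    accepted = 0
    bad_trajectories = 0
    for it in range(config.n_iterations):
        p0 = rng.standard_normal(target.dim)
        n_steps = int(rng.integers(lo, hi + 1))
        x_new, p_new = leapfrog(target, x, p0, eps, n_steps)
        u_new = target.energy(x_new)
        if np.isfinite(u_new):
            log_alpha = (u + 0.5 * p0 @ p0) - (u_new + 0.5 * p_new @ p_new)
            if np.log(rng.uniform()) < log_alpha:
                x, u = x_new, u_new
                accepted += 1
        else:
            bad_trajectories += 1
        if it >= config.burn_in:
            out[it - config.burn_in] = x
    if bad_trajectories:
        import warnings
        warnings.warn(f"{bad_trajectories} trajectories hit non-finite energy "
                      "and were rejected", RuntimeWarning, stacklevel=2)
    return out, accepted / config.n_iterations
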