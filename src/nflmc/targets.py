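"""Target distributions as energy functions.

Every target is a :class:`TargetDistribution` exposing the energy
``U(x) = -ln p_unnorm(x)``, its gradient and the diagonal of its Hessian,
all vectorized over a batch of points.  When the normalizing constant
``Z = ∫ exp(-U)`` is analytically known, ``log_norm_const`` stores ``ln Z``
so that normalized log-densities ``ln π(x) = -U(x) - ln Z`` are available;
otherwise consumers must work with log-ratios or supply a scale estimate.

The analytic catalog covers the benchmark families used to exercise the
sampler: ring-shaped densities, ill-conditioned and strongly correlated
Gaussians, Neal-style funnel, a "rough well" (quadratic bowl with
high-frequency cosine ripples), and two-component Gaussian mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .autodiff import value_grad_diag_hess

__all__ = [
    "TargetDistribution",
    "ring_energy",
    "rough_well_energy",
    "funnel_energy",
    "mog_energy",
    "make_ring",
    "make_rough_well",
    "make_funnel",
    "make_mog",
    "gaussian_target",
    "autodiff_wrap",
    "make_target",
    "TARGET_NAMES",
]


def _batch(x, dim):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        if x.shape[0] != dim:
            raise ValueError(f"expected dimension {dim}, got {x.shape[0]}")
        return x[None, :], True
    if x.ndim != 2 or x.shape[1] != dim:
        raise ValueError(f"expected (n, {dim}) array, got shape {x.shape}")
    return x, False


@dataclass
class TargetDistribution:
    """An unnormalized target ``p_unnorm(x) = exp(-U(x))``.

    ``energy``, ``grad_energy`` and ``diag_hess_energy`` operate on
    ``(n, dim)`` batches; the public methods also accept single vectors.
    ``hess_vec`` (full Hessian–vector product) is optional and only needed
    for reverse-mode training through the Langevin drift; targets without
    an analytic form fall back to a finite-difference product of
    ``grad_energy``.  ``hess_is_constant`` marks targets whose third
    derivatives vanish (Gaussians), letting training skip a correction term.
    """

    name: str
    dim: int
    _energy: Callable[[np.ndarray], np.ndarray]
    _grad: Callable[[np.ndarray], np.ndarray]
    _diag_hess: Callable[[np.ndarray], np.ndarray]
    log_norm_const: Optional[float] = None
    _hess_vec: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    hess_is_constant: bool = False
    _grad_diag: Optional[Callable[[np.ndarray], tuple]] = None
    # optional analytic cotangent of sum_i c_i * diag_hess(x)_i w.r.t. x
    _third_contract: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None

    def energy(self, x):
        xb, single = _batch(x, self.dim)
        u = self._energy(xb)
        return float(u[0]) if single else u

    def grad_energy(self, x):
        xb, single = _batch(x, self.dim)
        g = self._grad(xb)
        return g[0] if single else g

    def diag_hess_energy(self, x):
        xb, single = _batch(x, self.dim)
        h = self._diag_hess(xb)
        return h[0] if single else h

    def grad_and_diag_hess(self, x):
        """Gradient and Hessian diagonal in one pass (fused when available)."""
        xb, single = _batch(x, self.dim)
        if self._grad_diag is not None:
            g, h = self._grad_diag(xb)
        else:
            g, h = self._grad(xb), self._diag_hess(xb)
        return (g[0], h[0]) if single else (g, h)

    def hess_vec(self, x, v):
        """Full Hessian–vector product ``H(x) v``, batched."""
        xb, single = _batch(x, self.dim)
        vb, _ = _batch(v, self.dim)
        if self._hess_vec is not None:
            out = self._hess_vec(xb, vb)
        else:
            nrm = np.linalg.norm(vb, axis=1, keepdims=True)
            safe = np.where(nrm > 0, nrm, 1.0)
            step = 1e-5 * (1.0 + np.linalg.norm(xb, axis=1, keepdims=True)) / safe
            out = (self._grad(xb + step * vb) - self._grad(xb - step * vb)) / (2 * step)
            out = np.where(nrm > 0, out, 0.0)
        return out[0] if single else out

    def log_density(self, x):
        """Normalized ``ln π(x)``; requires a known normalizer."""
        if self.log_norm_const is None:
            raise ValueError(f"target '{self.name}' has unknown normalizer")
        return -self.energy(x) - self.log_norm_const


# ---------------------------------------------------------------------------
# closed-form energies
# ---------------------------------------------------------------------------

_RING_DIV = 0.32


def ring_energy(x, offset):
    """Ring-shaped energy ``(x1^2 + x2^2 - offset)^2 / 0.32`` in 2-D."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    xb, single = _batch(x, 2)
    r2 = np.sum(xb**2, axis=1)
    u = (r2 - offset) ** 2 / _RING_DIV
    return float(u[0]) if single else u


def make_ring(offset=2.0):
    offset = float(offset)
    if offset <= 0:
        raise ValueError("offset must be positive")

    def energy(xb):
        r2 = np.sum(xb**2, axis=1)
        return (r2 - offset) ** 2 / _RING_DIV

    def grad(xb):
        r2 = np.sum(xb**2, axis=1, keepdims=True)
        return 4.0 * xb * (r2 - offset) / _RING_DIV

    def diag_hess(xb):
        r2 = np.sum(xb**2, axis=1, keepdims=True)
        return (4.0 * (r2 - offset) + 8.0 * xb**2) / _RING_DIV

    def hess_vec(xb, vb):
        r2 = np.sum(xb**2, axis=1, keepdims=True)
        xv = np.sum(xb * vb, axis=1, keepdims=True)
        return (4.0 * (r2 - offset) * vb + 8.0 * xb * xv) / _RING_DIV

    return TargetDistribution("ring", 2, energy, grad, diag_hess,
                              _hess_vec=hess_vec)


def rough_well_energy(x, eta):
    """Quadratic well with cosine ripples: ``x·x/2 + η Σ cos(x_i/η)``."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    x = np.asarray(x, dtype=float)
    xb = x[None, :] if x.ndim == 1 else x
    u = 0.5 * np.sum(xb**2, axis=1) + eta * np.sum(np.cos(xb / eta), axis=1)
    return float(u[0]) if x.ndim == 1 else u


def make_rough_well(eta=1e-2, dim=2):
    eta = float(eta)
    if eta <= 0:
        raise ValueError("eta must be positive")

    def energy(xb):
        return 0.5 * np.sum(xb**2, axis=1) + eta * np.sum(np.cos(xb / eta), axis=1)

    def grad(xb):
        return xb - np.sin(xb / eta)

    def diag_hess(xb):
        return 1.0 - np.cos(xb / eta) / eta

    def hess_vec(xb, vb):  # Hessian is diagonal
        return diag_hess(xb) * vb

    return TargetDistribution("rough-well", dim, energy, grad, diag_hess,
                              _hess_vec=hess_vec)


def funnel_energy(x, sigma):
    """Neal-style 2-D funnel: ``x1 ~ N(0, σ²)``, ``x2 | x1 ~ N(0, e^{x1})``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    xb, single = _batch(x, 2)
    x1, x2 = xb[:, 0], xb[:, 1]
    u = x1**2 / (2 * sigma**2) + x2**2 * np.exp(-x1) / 2 + 0.5 * (np.log(2 * np.pi) + x1)
    return float(u[0]) if single else u


def make_funnel(sigma=1.0):
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    def energy(xb):
        x1, x2 = xb[:, 0], xb[:, 1]
        return (x1**2 / (2 * sigma**2) + x2**2 * np.exp(-x1) / 2
                + 0.5 * (np.log(2 * np.pi) + x1))

    def grad(xb):
        x1, x2 = xb[:, 0], xb[:, 1]
        e = np.exp(-x1)
        g1 = x1 / sigma**2 - x2**2 * e / 2 + 0.5
        g2 = x2 * e
        return np.stack([g1, g2], axis=1)

    def diag_hess(xb):
        x1, x2 = xb[:, 0], xb[:, 1]
        e = np.exp(-x1)
        return np.stack([1.0 / sigma**2 + x2**2 * e / 2, e], axis=1)

    def hess_vec(xb, vb):
        x1, x2 = xb[:, 0], xb[:, 1]
        e = np.exp(-x1)
        h11 = 1.0 / sigma**2 + x2**2 * e / 2
        h12 = -x2 * e
        out1 = h11 * vb[:, 0] + h12 * vb[:, 1]
        out2 = h12 * vb[:, 0] + e * vb[:, 1]
        return np.stack([out1, out2], axis=1)

    # exp(-U) integrates to sqrt(2 pi sigma^2): x2 conditional is normalized,
    # x1 factor is an unnormalized N(0, sigma^2).
    lnz = 0.5 * np.log(2 * np.pi * sigma**2)
    return TargetDistribution("funnel", 2, energy, grad, diag_hess,
                              log_norm_const=lnz, _hess_vec=hess_vec)


def mog_energy(x, weights, means):
    """Energy of a mixture of unit-covariance Gaussians, ``-ln Σ w_k N(x|μ_k, I)``."""
    return make_mog(weights, means).energy(x)


def make_mog(weights, means, name="mog"):
    w = np.asarray(weights, dtype=float)
    mu = np.asarray(means, dtype=float)
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("weights must be nonnegative and sum to 1")
    if mu.ndim != 2:
        raise ValueError("means must be a list of vectors")
    dim = mu.shape[1]
    logw = np.log(np.where(w > 0, w, 1e-300))
    cst = 0.5 * dim * np.log(2 * np.pi)

    def _log_comps(xb):
        # (n, K): ln w_k + ln N(x | mu_k, I)
        d2 = np.sum((xb[:, None, :] - mu[None, :, :]) ** 2, axis=2)
        return logw[None, :] - 0.5 * d2 - cst

    def _lse(lc):
        m = np.max(lc, axis=1, keepdims=True)
        return m + np.log(np.sum(np.exp(lc - m), axis=1, keepdims=True))

    def energy(xb):
        return -_lse(_log_comps(xb))[:, 0]

    def _resp(xb):
        lc = _log_comps(xb)
        return np.exp(lc - _lse(lc))

    def grad(xb):
        r = _resp(xb)  # (n, K)
        d = xb[:, None, :] - mu[None, :, :]
        return np.sum(r[:, :, None] * d, axis=1)

    def diag_hess(xb):
        r = _resp(xb)
        d = xb[:, None, :] - mu[None, :, :]
        m1 = np.sum(r[:, :, None] * d, axis=1)          # E_r[d]
        m2 = np.sum(r[:, :, None] * d**2, axis=1)       # E_r[d^2]
        return 1.0 - m2 + m1**2

    def grad_diag(xb):
        r = _resp(xb)
        d = xb[:, None, :] - mu[None, :, :]
        rc = r[:, :, None]
        m1 = np.sum(rc * d, axis=1)
        m2 = np.sum(rc * d**2, axis=1)
        return m1, 1.0 - m2 + m1**2

    def hess_vec(xb, vb):
        # H = I - E_r[d d^T] + E_r[d] E_r[d]^T
        r = _resp(xb)
        d = xb[:, None, :] - mu[None, :, :]
        dv = np.sum(d * vb[:, None, :], axis=2)          # (n, K)
        m1 = np.sum(r[:, :, None] * d, axis=1)
        m1v = np.sum(m1 * vb, axis=1, keepdims=True)
        return vb - np.sum((r * dv)[:, :, None] * d, axis=1) + m1 * m1v

    return TargetDistribution(name, dim, energy, grad, diag_hess,
                              log_norm_const=0.0, _hess_vec=hess_vec,
                              _grad_diag=grad_diag)


def gaussian_target(mean, cov, name="gaussian"):
    """Multivariate normal as a target; exact normalizer recorded."""
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    dim = mean.shape[0]
    eigvals = np.linalg.eigvalsh(cov)
    if np.any(eigvals <= 0):
        raise ValueError("covariance must be positive definite")
    prec = np.linalg.inv(cov)
    lnz = 0.5 * (dim * np.log(2 * np.pi) + np.linalg.slogdet(cov)[1])
    diag_prec = np.diag(prec)

    def energy(xb):
        d = xb - mean
        return 0.5 * np.sum((d @ prec) * d, axis=1)

    def grad(xb):
        return (xb - mean) @ prec

    def diag_hess(xb):
        return np.broadcast_to(diag_prec, xb.shape).copy()

    def hess_vec(xb, vb):
        return vb @ prec

    return TargetDistribution(name, dim, energy, grad, diag_hess,
                              log_norm_const=lnz, _hess_vec=hess_vec,
                              hess_is_constant=True)


def ill_conditioned_gaussian(dim=2):
    """Diagonal Gaussian with variances log-linearly spaced in [1e-2, 1e2]."""
    if dim < 2:
        raise ValueError("need dim >= 2")
    variances = np.logspace(-2, 2, dim)
    return gaussian_target(np.zeros(dim), np.diag(variances), name="icg")


def correlated_gaussian(mean_shift=False):
    """Diagonal Gaussian with variances (100, 0.01) rotated by π/4."""
    theta = np.pi / 4
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    cov = rot @ np.diag([100.0, 0.01]) @ rot.T
    mean = np.array([10.0, 10.0]) if mean_shift else np.zeros(2)
    return gaussian_target(mean, cov, name="scg-shifted" if mean_shift else "scg")


def autodiff_wrap(log_density_unnorm, dim, name="custom"):
    """Wrap a user-supplied unnormalized log-density into a target.

    The gradient and diagonal Hessian of ``U = -log_density_unnorm`` come
    from second-order forward-mode differentiation, so the callable must be
    written with jet-supported numpy operations (see :mod:`nflmc.autodiff`).
    """
    dim = int(dim)
    probe = log_density_unnorm(np.zeros(dim))
    if not np.isfinite(probe):
        raise ValueError(
            f"user log-density returned {probe!r} at the origin; "
            "wrap requires a finite value there")

    def energy(xb):
        return np.array([-float(log_density_unnorm(x)) for x in xb])

    def _vgh(x):
        return value_grad_diag_hess(log_density_unnorm, x)

    def grad(xb):
        return np.array([-_vgh(x)[1] for x in xb])

    def diag_hess(xb):
        return np.array([-_vgh(x)[2] for x in xb])

    return TargetDistribution(name, dim, energy, grad, diag_hess)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def make_target(name, **kwargs):
    """Catalog lookup by registry name (see ``TARGET_NAMES``)."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown target '{name}'; available: {', '.join(TARGET_NAMES)}"
        ) from None
    return factory(**kwargs)


_REGISTRY = {
    "ring": lambda **kw: make_ring(offset=kw.get("offset", 2.0)),
    "ring-large": lambda **kw: make_ring(offset=kw.get("offset", 3.0)),
    "icg": lambda **kw: ill_conditioned_gaussian(dim=kw.get("dim", 2)),
    "scg": lambda **kw: correlated_gaussian(mean_shift=False),
    "scg-shifted": lambda **kw: correlated_gaussian(mean_shift=True),
    "rough-well": lambda **kw: make_rough_well(eta=kw.get("eta", 1e-2),
                                               dim=kw.get("dim", 2)),
    "funnel": lambda **kw: make_funnel(sigma=kw.get("sigma", 1.0)),
    "mog1": lambda **kw: make_mog([0.5, 0.5], [[2.5, -2.5], [-2.5, 2.5]],
                                  name="mog1"),
    "mog2": lambda **kw: make_mog([0.88, 0.12], [[4.0, -4.0], [-4.0, 4.0]],
                                  name="mog2"),
}

TARGET_NAMES = tuple(_REGISTRY)
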