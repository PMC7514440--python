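"""Sampler-quality diagnostics.

Effective sample size follows the truncated-autocorrelation convention

    ESS = N / (1 + 2 * sum_{s=1}^{M} rho(s)),      M = 30 by default,

computed per dimension from the stationary single-mean autocorrelation
estimator.  The maximum mean discrepancy is the biased V-statistic (diagonal
terms included) with a Gaussian kernel whose bandwidth defaults to the
median pairwise distance of the pooled sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = ["DiagnosticsReport", "autocorrelation", "ess", "mmd2",
           "mode_weight", "diagnose"]

DEFAULT_MAX_LAG = 30

# ESS denominators can be nonpositive when negative autocorrelations
# dominate; they are clipped here and flagged in the report.
_DENOM_FLOOR = 1e-3


@dataclass
class DiagnosticsReport:
    acf: np.ndarray               # (max_lag + 1, D)
    ess_per_dim: np.ndarray       # (D,)
    ess_mean: float
    max_lag: int
    n: int
    mmd2: Optional[float] = None
    clipped_dims: list = field(default_factory=list)

    def to_dict(self):
        out = {"n": self.n, "max_lag": self.max_lag,
               "acf": self.acf.tolist(),
               "ess_per_dim": self.ess_per_dim.tolist(),
               "ess_mean": self.ess_mean,
               "clipped_dims": self.clipped_dims}
        if self.mmd2 is not None:
            out["mmd2"] = self.mmd2
        return out

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _as_chain(chain):
    chain = np.asarray(chain, dtype=float)
    if chain.ndim == 1:
        chain = chain[:, None]
    if chain.ndim != 2:
        raise ValueError("chain must be an (N, D) matrix")
    return chain


def autocorrelation(chain, max_lag=DEFAULT_MAX_LAG):
    """Per-dimension lagged autocorrelations rho(0..max_lag), (max_lag+1, D)."""
    chain = _as_chain(chain)
    n, d = chain.shape
    if not 1 <= max_lag < n:
        raise ValueError("need N > max_lag >= 1")
    centered = chain - chain.mean(axis=0)
    denom = np.sum(centered**2, axis=0)
    if np.any(denom == 0):
        raise ValueError("zero-variance chain: autocorrelation undefined")
    rho = np.empty((max_lag + 1, d))
    rho[0] = 1.0
    for s in range(1, max_lag + 1):
        rho[s] = np.sum(centered[:-s] * centered[s:], axis=0) / denom
    return rho


def ess(chain, max_lag=DEFAULT_MAX_LAG):
    """Per-dimension and mean effective sample size.

    Returns ``(ess_per_dim, ess_mean, clipped_dims)``; ``clipped_dims``
    lists dimensions whose denominator had to be floored.
    """
    chain = _as_chain(chain)
    n = chain.shape[0]
    rho = autocorrelation(chain, max_lag)
    denom = 1.0 + 2.0 * np.sum(rho[1:], axis=0)
    clipped = np.nonzero(denom < _DENOM_FLOOR)[0].tolist()
    denom = np.maximum(denom, _DENOM_FLOOR)
    per_dim = n / denom
    return per_dim, float(per_dim.mean()), clipped


def mmd2(x, y, kernel="rbf", bandwidth="median"):
    """Squared maximum mean discrepancy between two sample sets.

    Biased V-statistic with a Gaussian kernel
    ``k(a, b) = exp(-||a - b||^2 / (2 h^2))``; ``bandwidth="median"`` sets
    ``h`` to the median pairwise distance of the pooled points.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 0 or y.shape[0] == 0:
        raise ValueError("both sample sets must be nonempty")
    if x.shape[1] != y.shape[1]:
        raise ValueError(
            f"dimension mismatch: {x.shape[1]} vs {y.shape[1]}")
    if kernel != "rbf":
        raise ValueError("only the Gaussian ('rbf') kernel is supported")
    if bandwidth == "median":
        pooled = np.vstack([x, y])
        dists = pdist(pooled)
        med = np.median(dists[dists > 0]) if np.any(dists > 0) else 1.0
        h = med
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")

    def k(a, b):
        return np.exp(-cdist(a, b, "sqeuclidean") / (2 * h**2))

    m, n = x.shape[0], y.shape[0]
    return float(k(x, x).sum() / m**2
                 - 2.0 * k(x, y).sum() / (m * n)
                 + k(y, y).sum() / n**2)


def mode_weight(samples, mode_centers):
    """Fraction of samples nearer the first of two centers (ties count as first)."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    c1, c2 = (np.asarray(c, dtype=float) for c in mode_centers)
    if np.array_equal(c1, c2):
        raise ValueError("mode centers must be distinct")
    d1 = np.sum((samples - c1)**2, axis=1)
    d2 = np.sum((samples - c2)**2, axis=1)
    return float(np.mean(d1 <= d2))


def diagnose(chain, max_lag=DEFAULT_MAX_LAG, reference=None,
             bandwidth="median"):
    """Full report: ACF table, ESS, and MMD^2 against an optional reference."""
    chain = _as_chain(chain)
    rho = autocorrelation(chain, max_lag)
    per_dim, mean_ess, clipped = ess(chain, max_lag)
    m2 = mmd2(chain, reference, bandwidth=bandwidth) if reference is not None else None
    return DiagnosticsReport(acf=rho, ess_per_dim=per_dim, ess_mean=mean_ess,
                             max_lag=max_lag, n=chain.shape[0], mmd2=m2,
                             clipped_dims=clipped)
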