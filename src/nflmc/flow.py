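"""Langevin coupling layers and the stacked flow.

A coupling layer updates one coordinate block from the other in two half
updates.  Each half applies ``Ls - 1`` plain Langevin half-steps

    x_B <- x_B - (eps^2/2) * grad U(x)_B + eps * exp(sigma(x_A))

followed by one fused step that additionally rescales and shifts the block:

    y_B = (x_B - (eps^2/2) * grad U(x)_B + eps * exp(sigma(x_A)))
          * exp(S(x_A)) + T(x_A)

``sigma`` plays the role of the Brownian term of a Langevin diffusion, but
as a learned deterministic pseudo-noise, so the whole map is a deterministic
function of the base draw.  The Jacobian is block-triangular; its diagonal
is approximated elementwise by ``(1 - (eps^2/2) * H_ii) * exp(S_i)`` with
``H`` the target Hessian, which is exact whenever the Hessian is diagonal
on the updated block.

The inverse exists only approximately: the gradient in the update is
evaluated at a one-step surrogate point (``t1``/``t2``) computed without the
gradient term, giving an O(eps^2) reconstruction error.  The inverse
log-determinant uses ``exp(-S_i) * (1 + (eps^2/2) * H_ii)`` at the surrogate.

``backward`` implements reverse-mode differentiation of the forward pass and
its accumulated log-determinant with respect to the conditioner parameters,
which is all the squared-log-ratio training loss needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .nets import MLP
from .targets import TargetDistribution

__all__ = [
    "BaseDistribution",
    "ConditionerSet",
    "LangevinCouplingLayer",
    "FlowStack",
    "SampleBatch",
    "build_flow",
    "FlowSingularityError",
    "langevin_half_step",
    "forward_layer",
    "inverse_layer",
    "flow_log_prob",
    "sample_flow",
]

_SINGULAR_TOL = 1e-12

# sigma and S feed exp(); their raw network outputs are soft-clamped to
# cap * tanh(raw / cap) so a transient large activation cannot overflow.
SIGMA_CAP = 5.0
SCALE_CAP = 8.0

# Superlinear energies (e.g. quartic ring tails) make the explicit Langevin
# step unstable beyond a finite radius: one overshoot and subsequent drifts
# amplify to overflow.  The drift displacement (eps^2/2)*grad U is therefore
# capped elementwise; the cap is far outside any within-support displacement
# and the log-determinant treats capped coordinates as drift-free (their
# local drift derivative is zero).
DRIFT_CAP = 5.0


def _soft_clamp(raw, cap):
    """Value and derivative of the bounded rescaling cap*tanh(raw/cap)."""
    val = cap * np.tanh(raw / cap)
    return val, 1.0 - (val / cap) ** 2


class FlowSingularityError(RuntimeError):
    """Raised when a diagonal Jacobian factor vanishes; reduce the step size."""


@dataclass
class BaseDistribution:
    """Diagonal Gaussian base (proposal) distribution."""

    mean: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.scale = np.broadcast_to(
            np.asarray(self.scale, dtype=float), self.mean.shape).copy()
        if np.any(self.scale <= 0):
            raise ValueError("scale must be positive")

    @property
    def dim(self):
        return self.mean.shape[0]

    def sample(self, n, rng):
        return self.mean + self.scale * rng.standard_normal((n, self.dim))

    def log_prob(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.mean) / self.scale
        return (-0.5 * np.sum(z**2, axis=1)
                - np.sum(np.log(self.scale))
                - 0.5 * self.dim * np.log(2 * np.pi))


class ConditionerSet:
    """The three learned maps sigma, S, T of one half-update.

    ``sigma_init`` sets the final bias of the sigma net: the pseudo-noise
    starts at ``eps * exp(sigma_init)`` everywhere.  A negative value damps
    it so a freshly built layer is dominated by the Langevin drift rather
    than by a systematic positive offset.  ``scale_init`` likewise seeds the
    S net's final bias, pre-expanding the block to offset the volume
    contraction of repeated drift steps.
    """

    def __init__(self, n_in, n_out, hidden, rng, sigma_init=0.0,
                 scale_init=0.0):
        sizes = [n_in, *hidden, n_out]
        self.sigma = MLP(sizes, rng)
        self.sigma.b[-1][...] = sigma_init
        self.scale = MLP(sizes, rng)
        self.scale.b[-1][...] = scale_init
        self.shift = MLP(sizes, rng)

    @property
    def nets(self):
        return (self.sigma, self.scale, self.shift)

    def state_dict(self):
        return {"sigma": self.sigma.state_dict(),
                "scale": self.scale.state_dict(),
                "shift": self.shift.state_dict()}

    @classmethod
    def from_state(cls, state):
        c = cls.__new__(cls)
        c.sigma = MLP.from_state(state["sigma"])
        c.scale = MLP.from_state(state["scale"])
        c.shift = MLP.from_state(state["shift"])
        return c


@dataclass
class SampleBatch:
    """Draws plus their flow log-density and unnormalized target log-density."""

    points: np.ndarray
    log_q_flow: np.ndarray
    log_target_unnorm: np.ndarray

    def __post_init__(self):
        n = self.points.shape[0]
        if not (len(self.log_q_flow) == len(self.log_target_unnorm) == n):
            raise ValueError("row counts of batch fields disagree")

    def __len__(self):
        return self.points.shape[0]


def _dh_contract(target, x, c):
    """Cotangent of ``sum_i c_i * diag_hess(x)_i`` w.r.t. ``x`` (batched).

    Third derivatives of the catalog energies are not provided in closed
    form; a central finite difference of the diagonal Hessian along each
    axis is accurate far beyond the training tolerance.
    """
    if target.hess_is_constant:
        return np.zeros_like(x)
    if target._third_contract is not None:
        return target._third_contract(x, c)
    n, d = x.shape
    steps = 1e-4 * (1.0 + np.abs(x))                       # (n, d)
    # one stacked evaluation: for each axis j, rows perturbed +/- along j
    probes = np.tile(x, (2 * d, 1))
    for j in range(d):
        probes[j * n:(j + 1) * n, j] += steps[:, j]
        probes[(d + j) * n:(d + j + 1) * n, j] -= steps[:, j]
    hs = target.diag_hess_energy(probes)
    out = np.empty_like(x)
    for j in range(d):
        dh = hs[j * n:(j + 1) * n] - hs[(d + j) * n:(d + j + 1) * n]
        out[:, j] = np.sum(c * dh, axis=1) / (2 * steps[:, j])
    return out


class LangevinCouplingLayer:
    """One coupling layer; ``swap`` flips which block is updated first."""

    def __init__(self, target: TargetDistribution, epsilon, langevin_steps,
                 split_index, hidden, rng, swap=False, sigma_init=0.0,
                 scale_init=0.0):
        if target.dim < 2:
            raise ValueError("coupling layers need dimension >= 2")
        if langevin_steps < 1:
            raise ValueError("langevin_steps must be >= 1")
        if not 1 <= split_index < target.dim:
            raise ValueError("split index must satisfy 1 <= d < D")
        if epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        self.target = target
        self.epsilon = float(epsilon)
        self.langevin_steps = int(langevin_steps)
        self.split_index = int(split_index)
        self.swap = bool(swap)
        d, dim = self.split_index, target.dim
        self.idx_lower = np.arange(0, d)
        self.idx_upper = np.arange(d, dim)
        first_upd, first_cond = ((self.idx_lower, self.idx_upper) if swap
                                 else (self.idx_upper, self.idx_lower))
        self.conditioners_first = ConditionerSet(
            len(first_cond), len(first_upd), hidden, rng,
            sigma_init=sigma_init, scale_init=scale_init)
        self.conditioners_second = ConditionerSet(
            len(first_upd), len(first_cond), hidden, rng,
            sigma_init=sigma_init, scale_init=scale_init)

    # ------------------------------------------------------------------
    def _halves(self):
        """(idx_upd, idx_cond, conditioners) for the two half-updates in order."""
        if self.swap:
            return ((self.idx_lower, self.idx_upper, self.conditioners_first),
                    (self.idx_upper, self.idx_lower, self.conditioners_second))
        return ((self.idx_upper, self.idx_lower, self.conditioners_first),
                (self.idx_lower, self.idx_upper, self.conditioners_second))

    def _grad_hess_block(self, x, idx):
        if self.epsilon == 0.0:
            nb = (x.shape[0], len(idx))
            return np.zeros(nb), np.zeros(nb)
        g, h = self.target.grad_and_diag_hess(x)
        if not np.all(np.isfinite(g)):
            bad = np.argwhere(~np.isfinite(g))
            raise FloatingPointError(
                f"non-finite target gradient at coordinates {bad[:5].tolist()}")
        return g[:, idx], h[:, idx]

    def _drift_block(self, x, idx):
        """Capped drift displacement, effective Hessian diagonal, cap mask."""
        gb, hb = self._grad_hess_block(x, idx)
        drift = 0.5 * self.epsilon**2 * gb
        capped = np.abs(drift) > DRIFT_CAP
        if capped.any():
            drift = np.clip(drift, -DRIFT_CAP, DRIFT_CAP)
            hb = np.where(capped, 0.0, hb)
        return drift, hb, capped

    @staticmethod
    def _check_factor(factor):
        if np.any(np.abs(factor) < _SINGULAR_TOL):
            raise FlowSingularityError(
                "diagonal Jacobian factor |1 - (eps^2/2) H_ii| vanished; "
                "use a smaller step size epsilon")

    # -- forward -------------------------------------------------------
    def _half_forward(self, x, idx_upd, idx_cond, cond, tape):
        eps, eps2h = self.epsilon, 0.5 * self.epsilon**2
        x = x.copy()
        xa = x[:, idx_cond]
        sa_raw, sigma_cache = cond.sigma.forward(xa)
        sa, dsa = _soft_clamp(sa_raw, SIGMA_CAP)
        eexp = eps * np.exp(sa)
        ld = np.zeros(x.shape[0])
        steps = []
        for _ in range(self.langevin_steps - 1):
            drift, hb, capped = self._drift_block(x, idx_upd)
            factor = 1.0 - eps2h * hb
            self._check_factor(factor)
            steps.append(("pure", x.copy(), hb, capped))
            x[:, idx_upd] = x[:, idx_upd] - drift + eexp
            ld += np.sum(np.log(np.abs(factor)), axis=1)
        drift, hb, capped = self._drift_block(x, idx_upd)
        factor = 1.0 - eps2h * hb
        self._check_factor(factor)
        sv_raw, s_cache = cond.scale.forward(xa)
        sv, dsv = _soft_clamp(sv_raw, SCALE_CAP)
        tv, t_cache = cond.shift.forward(xa)
        u = x[:, idx_upd] - drift + eexp
        steps.append(("fused", x.copy(), hb, capped, u, sv))
        y = x.copy()
        y[:, idx_upd] = u * np.exp(sv) + tv
        ld += np.sum(np.log(np.abs(factor)) + sv, axis=1)
        if tape is not None:
            tape.append({"idx_upd": idx_upd, "idx_cond": idx_cond, "cond": cond,
                         "sigma_cache": sigma_cache, "s_cache": s_cache,
                         "t_cache": t_cache, "eexp": eexp, "dsa": dsa,
                         "dsv": dsv, "steps": steps})
        return y, ld

    def forward(self, x, tape=None):
        """Push a batch through the layer; returns ``(z, fwd_logdet)``."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        ld = np.zeros(x.shape[0])
        for idx_upd, idx_cond, cond in self._halves():
            x, ld_half = self._half_forward(x, idx_upd, idx_cond, cond, tape)
            ld += ld_half
        return x, ld

    # -- inverse -------------------------------------------------------
    def _half_inverse(self, z, idx_upd, idx_cond, cond):
        eps, eps2h = self.epsilon, 0.5 * self.epsilon**2
        z = z.copy()
        za = z[:, idx_cond]
        sa, _ = _soft_clamp(cond.sigma(za), SIGMA_CAP)
        sv, _ = _soft_clamp(cond.scale(za), SCALE_CAP)
        tv = cond.shift(za)
        eexp = eps * np.exp(sa)
        ld = np.zeros(z.shape[0])
        # fused step first (it was applied last in the forward direction)
        t = (z[:, idx_upd] - tv) * np.exp(-sv) - eexp
        surro = z.copy()
        surro[:, idx_upd] = t
        drift, hb, _ = self._drift_block(surro, idx_upd)
        factor = 1.0 + eps2h * hb
        self._check_factor(factor)
        z[:, idx_upd] = t + drift
        ld += np.sum(-sv + np.log(np.abs(factor)), axis=1)
        for _ in range(self.langevin_steps - 1):
            t = z[:, idx_upd] - eexp
            surro = z.copy()
            surro[:, idx_upd] = t
            drift, hb, _ = self._drift_block(surro, idx_upd)
            factor = 1.0 + eps2h * hb
            self._check_factor(factor)
            z[:, idx_upd] = t + drift
            ld += np.sum(np.log(np.abs(factor)), axis=1)
        return z, ld

    def inverse(self, z):
        """Pull a batch back through the layer; returns ``(x, inv_logdet)``."""
        z = np.atleast_2d(np.asarray(z, dtype=float))
        ld = np.zeros(z.shape[0])
        for idx_upd, idx_cond, cond in reversed(self._halves()):
            z, ld_half = self._half_inverse(z, idx_upd, idx_cond, cond)
            ld += ld_half
        return z, ld

    # -- reverse-mode --------------------------------------------------
    def _half_backward(self, rec, xbar, lbar):
        eps, eps2h = self.epsilon, 0.5 * self.epsilon**2
        idx_upd, idx_cond, cond = rec["idx_upd"], rec["idx_cond"], rec["cond"]
        eexp = rec["eexp"]
        xbar = xbar.copy()
        sa_bar = np.zeros_like(eexp)
        cond_in_bar = np.zeros((xbar.shape[0], len(idx_cond)))
        for step in reversed(rec["steps"]):
            if step[0] == "fused":
                _, x0, hb, capped, u, sv = step
                ybar = xbar[:, idx_upd]
                cond_in_bar += cond.shift.backward(rec["t_cache"], ybar)
                sbar = ybar * u * np.exp(sv) + lbar[:, None]
                cond_in_bar += cond.scale.backward(rec["s_cache"],
                                                   sbar * rec["dsv"])
                ubar = ybar * np.exp(sv)
            else:
                _, x0, hb, capped = step
                ubar = xbar[:, idx_upd]
            sa_bar += ubar * eexp
            xbar[:, idx_upd] = ubar
            if self.epsilon != 0.0:
                # capped coordinates carry no drift derivative
                v = np.zeros_like(xbar)
                v[:, idx_upd] = np.where(capped, 0.0, -eps2h * ubar)
                xbar += self.target.hess_vec(x0, v)
                c = np.zeros_like(xbar)
                c[:, idx_upd] = np.where(
                    capped, 0.0,
                    lbar[:, None] * (-eps2h) / (1.0 - eps2h * hb))
                xbar += _dh_contract(self.target, x0, c)
        cond_in_bar += cond.sigma.backward(rec["sigma_cache"],
                                           sa_bar * rec["dsa"])
        xbar[:, idx_cond] += cond_in_bar
        return xbar

    def backward(self, tape_entries, xbar, lbar):
        """Backprop through this layer's two recorded half-updates."""
        for rec in reversed(tape_entries):
            xbar = self._half_backward(rec, xbar, lbar)
        return xbar

    @property
    def conditioner_nets(self):
        return [n for c in (self.conditioners_first, self.conditioners_second)
                for n in c.nets]

    def state_dict(self):
        return {"epsilon": self.epsilon,
                "langevin_steps": self.langevin_steps,
                "split_index": self.split_index,
                "swap": self.swap,
                "conditioners_first": self.conditioners_first.state_dict(),
                "conditioners_second": self.conditioners_second.state_dict()}


class FlowStack:
    """Composition of coupling layers over a diagonal-Gaussian base."""

    def __init__(self, layers: List[LangevinCouplingLayer], base: BaseDistribution):
        if not layers:
            raise ValueError("need at least one layer")
        dims = {layer.target.dim for layer in layers}
        if dims != {base.dim}:
            raise ValueError("layer and base dimensions disagree")
        self.layers = layers
        self.base = base

    @property
    def dim(self):
        return self.base.dim

    @property
    def target(self):
        return self.layers[0].target

    def forward(self, x, tapes: Optional[list] = None):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        ld = np.zeros(x.shape[0])
        for layer in self.layers:
            if tapes is not None:
                tape = []
                tapes.append(tape)
            else:
                tape = None
            x, ld_layer = layer.forward(x, tape=tape)
            ld += ld_layer
        return x, ld

    def inverse(self, z):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        ld = np.zeros(z.shape[0])
        for layer in reversed(self.layers):
            z, ld_layer = layer.inverse(z)
            ld += ld_layer
        return z, ld

    def backward(self, tapes, zbar, lbar):
        for layer, tape in zip(reversed(self.layers), reversed(tapes)):
            zbar = layer.backward(tape, zbar, lbar)
        return zbar

    def log_prob(self, z):
        """``ln pi_u(z)`` via the inverse pass and its log-determinant."""
        x0, inv_ld = self.inverse(z)
        return self.base.log_prob(x0) + inv_ld

    def sample(self, n, seed=None, rng=None):
        if n < 1:
            raise ValueError("need n >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        x0 = self.base.sample(n, rng)
        z, _ = self.forward(x0)
        return SampleBatch(points=z,
                           log_q_flow=self.log_prob(z),
                           log_target_unnorm=-self.target.energy(z))

    # -- parameters ----------------------------------------------------
    @property
    def conditioner_nets(self):
        return [n for layer in self.layers for n in layer.conditioner_nets]

    @property
    def params(self):
        return [p for net in self.conditioner_nets for p in net.params]

    @property
    def grads(self):
        return [g for net in self.conditioner_nets for g in net.grads]

    def zero_grad(self):
        for net in self.conditioner_nets:
            net.zero_grad()

    def state_dict(self):
        return {"base_mean": self.base.mean.tolist(),
                "base_scale": self.base.scale.tolist(),
                "layers": [layer.state_dict() for layer in self.layers]}


def build_flow(target, num_layers=4, hidden=(64, 64), epsilon=0.05,
               langevin_steps=2, base=None, seed=0, split_index=None,
               sigma_init=0.0, scale_init=0.0):
    """Assemble a flow whose layers alternate which block updates first."""
    if base is None:
        base = BaseDistribution(np.zeros(target.dim), np.ones(target.dim))
    if split_index is None:
        split_index = target.dim // 2
    rng = np.random.default_rng(seed)
    layers = [LangevinCouplingLayer(target, epsilon, langevin_steps,
                                    split_index, hidden, rng,
                                    swap=bool(i % 2), sigma_init=sigma_init,
                                    scale_init=scale_init)
              for i in range(num_layers)]
    return FlowStack(layers, base)


def load_flow(state, target):
    """Rebuild a stack from ``state_dict`` output (weights included)."""
    base = BaseDistribution(np.asarray(state["base_mean"]),
                            np.asarray(state["base_scale"]))
    layers = []
    rng = np.random.default_rng(0)
    for ls in state["layers"]:
        layer = LangevinCouplingLayer(
            target, ls["epsilon"], ls["langevin_steps"], ls["split_index"],
            hidden=(1,), rng=rng, swap=ls["swap"])
        layer.conditioners_first = ConditionerSet.from_state(
            ls["conditioners_first"])
        layer.conditioners_second = ConditionerSet.from_state(
            ls["conditioners_second"])
        layers.append(layer)
    return FlowStack(layers, base)


# ---------------------------------------------------------------------------
# functional wrappers (single-vector convenience API)
# ---------------------------------------------------------------------------

def langevin_half_step(x, block, layer):
    """One plain Langevin half-update of the named block ('first'/'second')."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    if block == "second":
        idx_upd, idx_cond = layer.idx_upper, layer.idx_lower
    elif block == "first":
        idx_upd, idx_cond = layer.idx_lower, layer.idx_upper
    else:
        raise ValueError("block must be 'first' or 'second'")
    cond = (layer.conditioners_first if (block == "second") != layer.swap
            else layer.conditioners_second)
    eps = layer.epsilon
    sa, _ = _soft_clamp(cond.sigma(xb[:, idx_cond]), SIGMA_CAP)
    drift, _, _ = layer._drift_block(xb, idx_upd)
    out = xb.copy()
    out[:, idx_upd] = xb[:, idx_upd] - drift + eps * np.exp(sa)
    return out[0] if single else out


def forward_layer(x, layer):
    x = np.asarray(x, dtype=float)
    z, ld = layer.forward(x)
    return (z[0], float(ld[0])) if x.ndim == 1 else (z, ld)


def inverse_layer(z, layer):
    z = np.asarray(z, dtype=float)
    x, ld = layer.inverse(z)
    return (x[0], float(ld[0])) if z.ndim == 1 else (x, ld)


def flow_log_prob(z, stack):
    z = np.asarray(z, dtype=float)
    lp = stack.log_prob(z)
    return float(lp[0]) if z.ndim == 1 else lp


def sample_flow(stack, n, seed):
    return stack.sample(n, seed=seed)
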