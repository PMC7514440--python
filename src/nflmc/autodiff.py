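"""Forward-mode automatic differentiation with second-order jets.

A :class:`Jet` carries a value together with the first and second directional
derivatives along a single direction, i.e. it represents the truncated Taylor
expansion ``f(x + t v) = f0 + f1 t + f2 t^2 / 2``.  Seeding the coordinate
directions one at a time yields the gradient and the diagonal of the Hessian
of a scalar field in ``D`` forward passes — exactly what the Langevin coupling
layers need from a target energy (``grad`` and elementwise ``hess``).

Only the operations commonly appearing in log-density code are supported
(arithmetic, powers, exp/log/sqrt, trigonometric and hyperbolic functions,
``np.sum``/``np.dot``/``@``).  Anything else raises ``TypeError``, which is
the intended signal that a user-supplied density is not differentiable by
this machinery.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Jet", "value_grad_diag_hess", "grad", "diag_hess"]


def _as_jet(other):
    if isinstance(other, Jet):
        return other
    return Jet(np.asarray(other, dtype=float), 0.0, 0.0)


class Jet:
    """Second-order truncated Taylor number along one direction."""

    __array_priority__ = 1000  # numpy defers binary ops to Jet

    def __init__(self, f0, f1=0.0, f2=0.0):
        self.f0 = np.asarray(f0, dtype=float)
        self.f1 = np.broadcast_to(np.asarray(f1, dtype=float), self.f0.shape).copy()
        self.f2 = np.broadcast_to(np.asarray(f2, dtype=float), self.f0.shape).copy()

    # -- structural ----------------------------------------------------
    def __getitem__(self, idx):
        return Jet(self.f0[idx], self.f1[idx], self.f2[idx])

    def __len__(self):
        return len(self.f0)

    @property
    def shape(self):
        return self.f0.shape

    def sum(self, *a, **k):
        return Jet(self.f0.sum(*a, **k), self.f1.sum(*a, **k), self.f2.sum(*a, **k))

    def __iter__(self):
        for i in range(len(self.f0)):
            yield self[i]

    # -- arithmetic ----------------------------------------------------
    def __neg__(self):
        return Jet(-self.f0, -self.f1, -self.f2)

    def __add__(self, other):
        o = _as_jet(other)
        return Jet(self.f0 + o.f0, self.f1 + o.f1, self.f2 + o.f2)

    __radd__ = __add__

    def __sub__(self, other):
        return self + (-_as_jet(other))

    def __rsub__(self, other):
        return _as_jet(other) + (-self)

    def __mul__(self, other):
        o = _as_jet(other)
        return Jet(
            self.f0 * o.f0,
            self.f1 * o.f0 + self.f0 * o.f1,
            self.f2 * o.f0 + 2.0 * self.f1 * o.f1 + self.f0 * o.f2,
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_jet(other)._reciprocal()

    def __rtruediv__(self, other):
        return _as_jet(other) * self._reciprocal()

    def _reciprocal(self):
        inv = 1.0 / self.f0
        d1 = -inv * inv * self.f1
        d2 = -inv * inv * self.f2 + 2.0 * inv**3 * self.f1**2
        return Jet(inv, d1, d2)

    def __pow__(self, p):
        if isinstance(p, Jet):
            raise TypeError("Jet exponents are not supported")
        p = float(p)
        v = self.f0**p
        d1 = p * self.f0 ** (p - 1.0)
        d2 = p * (p - 1.0) * self.f0 ** (p - 2.0)
        return self._chain(v, d1, d2)

    def _chain(self, v, d1, d2):
        """Apply a scalar function given value and its first two derivatives."""
        return Jet(v, d1 * self.f1, d2 * self.f1**2 + d1 * self.f2)

    def __matmul__(self, other):
        o = _as_jet(other)
        return (self * o).sum()

    __rmatmul__ = __matmul__

    # -- ufunc dispatch -------------------------------------------------
    _UNARY = {
        np.exp: lambda v: (np.exp(v), np.exp(v), np.exp(v)),
        np.log: lambda v: (np.log(v), 1.0 / v, -1.0 / v**2),
        np.sqrt: lambda v: (np.sqrt(v), 0.5 / np.sqrt(v), -0.25 * v**-1.5),
        np.sin: lambda v: (np.sin(v), np.cos(v), -np.sin(v)),
        np.cos: lambda v: (np.cos(v), -np.sin(v), -np.cos(v)),
        np.tan: lambda v: (np.tan(v), 1 + np.tan(v) ** 2,
                           2 * np.tan(v) * (1 + np.tan(v) ** 2)),
        np.tanh: lambda v: (np.tanh(v), 1 - np.tanh(v) ** 2,
                            -2 * np.tanh(v) * (1 - np.tanh(v) ** 2)),
        np.cosh: lambda v: (np.cosh(v), np.sinh(v), np.cosh(v)),
        np.sinh: lambda v: (np.sinh(v), np.cosh(v), np.sinh(v)),
        np.negative: None,
        np.square: None,
    }

    def __array_ufunc__(self, ufunc, method, *inputs, **kwargs):
        if method == "reduce" and ufunc is np.add:
            (arg,) = inputs
            return arg.sum(**{k: v for k, v in kwargs.items() if k == "axis"})
        if method != "__call__" or kwargs.get("out") is not None:
            return NotImplemented
        if ufunc is np.negative:
            return -inputs[0]
        if ufunc is np.square:
            return inputs[0] * inputs[0]
        if ufunc in (np.add, np.subtract, np.multiply, np.true_divide, np.power):
            a, b = inputs
            op = {np.add: Jet.__add__, np.subtract: Jet.__sub__,
                  np.multiply: Jet.__mul__, np.true_divide: Jet.__truediv__,
                  np.power: Jet.__pow__}[ufunc]
            if not isinstance(a, Jet):
                a, b = _as_jet(a), b
                # rewire reflected form
                if ufunc is np.subtract:
                    return a - b
                if ufunc is np.true_divide:
                    return a / b
                if ufunc is np.power:
                    raise TypeError("Jet exponents are not supported")
            return op(a, b if isinstance(b, Jet) else _as_jet(b))
        rule = self._UNARY.get(ufunc)
        if rule is None:
            return NotImplemented
        (arg,) = inputs
        v, d1, d2 = rule(arg.f0)
        return arg._chain(v, d1, d2)


def value_grad_diag_hess(f, x):
    """Value, gradient and diagonal Hessian of scalar field ``f`` at ``x``.

    ``f`` must accept a length-``D`` vector-like object and return a scalar,
    using only jet-supported operations.  One forward pass per coordinate.
    """
    x = np.asarray(x, dtype=float)
    d = x.shape[0]
    g = np.empty(d)
    h = np.empty(d)
    val = None
    for i in range(d):
        seed = np.zeros(d)
        seed[i] = 1.0
        out = f(Jet(x, seed))
        if not isinstance(out, Jet):  # constant field along this direction
            out = _as_jet(out)
        val = float(np.asarray(out.f0))
        g[i] = float(np.asarray(out.f1))
        h[i] = float(np.asarray(out.f2))
    if val is None:
        raise ValueError("zero-dimensional input")
    return val, g, h


def grad(f, x):
    return value_grad_diag_hess(f, x)[1]


def diag_hess(f, x):
    return value_grad_diag_hess(f, x)[2]
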