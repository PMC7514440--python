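"""Small fully connected networks with hand-written reverse-mode backprop.

The conditioners of a coupling layer are plain ReLU multilayer perceptrons.
Each :class:`MLP` owns its weights, accumulates parameter gradients in-place
(``.grads``), and exposes ``forward``/``backward`` in the usual tape style:
``forward`` returns the output plus a cache of activations, ``backward``
consumes the cache and the output cotangent and returns the input cotangent.

The last layer is initialized to zero so a freshly built coupling layer is
the identity map (up to its Langevin drift), which keeps early training in a
well-conditioned regime.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP"]


class MLP:
    def __init__(self, sizes, rng, zero_last=True):
        """``sizes`` is ``[n_in, hidden..., n_out]``."""
        self.sizes = list(sizes)
        self.W = []
        self.b = []
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = i == len(sizes) - 2
            if last and zero_last:
                w = np.zeros((n_in, n_out))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
            self.W.append(w)
            self.b.append(np.zeros(n_out))
        self.gW = [np.zeros_like(w) for w in self.W]
        self.gb = [np.zeros_like(b) for b in self.b]

    # -- parameter plumbing -------------------------------------------
    @property
    def params(self):
        return self.W + self.b

    @property
    def grads(self):
        return self.gW + self.gb

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0

    def state_dict(self):
        return {"sizes": self.sizes,
                "W": [w.tolist() for w in self.W],
                "b": [b.tolist() for b in self.b]}

    @classmethod
    def from_state(cls, state):
        net = cls.__new__(cls)
        net.sizes = list(state["sizes"])
        net.W = [np.asarray(w, dtype=float) for w in state["W"]]
        net.b = [np.asarray(b, dtype=float) for b in state["b"]]
        net.gW = [np.zeros_like(w) for w in net.W]
        net.gb = [np.zeros_like(b) for b in net.b]
        return net

    # -- forward / backward -------------------------------------------
    def forward(self, x):
        """``x``: (n, n_in).  Returns output (n, n_out) and a cache."""
        acts = [x]
        h = x
        n_layers = len(self.W)
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            h = h @ w + b
            if i < n_layers - 1:
                h = np.maximum(h, 0.0)
            acts.append(h)
        return h, acts

    def __call__(self, x):
        return self.forward(x)[0]

    def backward(self, cache, dout):
        """Accumulate parameter grads; return cotangent w.r.t. the input."""
        acts = cache
        g = dout
        for i in range(len(self.W) - 1, -1, -1):
            if i < len(self.W) - 1:
                g = g * (acts[i + 1] > 0)  # ReLU mask
            self.gW[i] += acts[i].T @ g
            self.gb[i] += g.sum(axis=0)
            g = g @ self.W[i].T
        return g
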