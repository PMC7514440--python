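# nflmc — Langevin normalizing-flow Monte Carlo

`nflmc` draws independent samples from an unnormalized probability
distribution by *training* a deterministic sampler, instead of running a
Markov chain.  It is aimed at Bayesian posterior sampling — the bundled
application is Bayesian logistic regression — and at difficult analytic
targets (ill-conditioned and strongly correlated Gaussians, ring-shaped
densities, funnels, well-separated Gaussian mixtures) where
gradient-informed MCMC mixes poorly or fails to move between modes.

## The method

A target is specified by its energy `U(x) = −ln p_unnorm(x)`.  An invertible
map `f_θ` — a stack of coupling layers — pushes a diagonal-Gaussian base
`q` onto the target.  Each coupling layer embeds Euler–Maruyama Langevin
steps in its block update,

    y_B = (x_B − (ε²/2) ∇U(x)_B + ε·e^{σ(x_A)}) ⊙ e^{S(x_A)} + T(x_A),

where the drift `−(ε²/2)∇U` pulls samples toward high-probability regions
and `σ`, `S`, `T` are small neural networks (the "noise" `ε·e^σ` is learned
and deterministic).  The Jacobian is block-triangular with elementwise
diagonal `(1 − (ε²/2) ∂²U/∂x_i²)·e^{S_i}`, so the flow's log-density is
tractable; the inverse uses a one-step surrogate accurate to O(ε²).

Training minimizes the squared log-density ratio over the flow's own draws

    L(θ) = E_{π_u}[(ln γ + ln π_u(x) − ln p_unnorm(x))²],

which is nonnegative on every batch and reaches 0 exactly at `π_u = π_t`
with `γ = Z`.  For targets with unknown normalizer, `γ` is estimated once
by importance sampling.  Sampling from the trained flow needs no
Metropolis–Hastings correction, so draws are uncorrelated by construction
(effective sample size ≈ nominal N).

MALA and HMC baseline chains, plus diagnostics (lagged autocorrelation,
effective sample size with `ESS = N/(1+2Σ_{s≤30}ρ(s))`, kernel MMD², mode
weights) share the same target objects and sample-file format.

## Worked example

Train the reduced-profile sampler on the asymmetric two-mode Gaussian
mixture (modes at ±(4,−4), weights 0.88/0.12 — a configuration where HMC
gets trapped in one basin) and audit the recovered mode masses:

```python
import numpy as np
from nflmc.experiments import train_catalog_target
from nflmc.diagnostics import mode_weight, ess

state = train_catalog_target("mog2", seed=1)
print(f"final loss {np.mean(state.loss_trace[-50:]):.3f}")

batch = state.stack.sample(8000, seed=1)
frac = mode_weight(batch.points, ([4, -4], [-4, 4]))
print(f"dominant-mode mass {frac:.3f} (true 0.88)")
print(f"mean ESS {ess(batch.points)[1]:.0f} of 8000")
```

```
final loss 0.537
dominant-mode mass 0.903 (true 0.88)
mean ESS 8923 of 8000
```

The trained flow recovers the 0.88/0.12 mode split to a few percent from
8000 independent draws — at this reduced profile the residual density
misfit leaves the recovered mass a few points off, see `docs/methods.md` —
and the effective sample size sits at the nominal N (the truncated-ACF
estimator fluctuates around and even above N for independent draws, while
an MCMC chain on this target has ESS far below N, when it crosses between
modes at all).

The same machinery runs from the shell: `nflmc train`, `nflmc sample
--method nflmc|mala|hmc`, `nflmc diagnose`, and `nflmc blr` (logistic
regression on a delimited table).  See `nflmc --help`.

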