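# Methods

## Model

`nflmc` trains a deterministic, invertible map `f_θ` that pushes a simple
base distribution `q` (a diagonal Gaussian) onto a target `π_t` known only
through an energy `U(x) = −ln p_unnorm(x)`.  Samples are obtained by drawing
`x₀ ∼ q` and computing `z = f_θ(x₀)`; no Metropolis–Hastings correction is
applied, so draws are i.i.d. under the *learned* density `π_u`, and sampler
quality is exactly the quality of the fit `π_u ≈ π_t`.

### Coupling layers with Langevin drift

Each of the `T` layers splits the coordinates at `d = ⌊D/2⌋` and updates one
block from the other in two half-updates.  A half-update applies `Ls − 1`
plain Langevin half-steps

    x_B ← x_B − (ε²/2) ∇U(x)_B + ε·exp(σ(x_A)),

followed by one fused step that also rescales and shifts,

    y_B = (x_B − (ε²/2) ∇U(x)_B + ε·exp(σ(x_A))) ⊙ exp(S(x_A)) + T(x_A).

The drift `−(ε²/2)∇U` is the Euler–Maruyama discretization of a Langevin
diffusion with stationary law `π_t`; the Brownian increment is replaced by
the *learned*, strictly positive pseudo-noise `ε·exp(σ(·))`, keeping the map
deterministic.  `σ`, `S`, `T` are independent ReLU networks per half-update
(no weight sharing across layers); their final layers start at zero so every
layer begins as the pure-Langevin map.  Layers alternate which block updates
first.  With `ε = 0` the architecture reduces exactly to an affine coupling
flow (the "NNFMC" ablation).

### Jacobians and the approximate inverse

The update is block-triangular, and its diagonal is approximated
elementwise:

    fwd logdet = Σ_i ln|(1 − (ε²/2) H_ii) · exp(S_i)|   (fused step)
                 Σ_i ln|1 − (ε²/2) H_ii|                 (plain step)

with `H_ii` the target Hessian diagonal `∂²U/∂x_i²` at the step's input.
Off-diagonal curvature *within* the updated block is ignored; the
approximation is exact whenever the Hessian is diagonal on that block
(verified against full finite-difference Jacobians on such targets, ≤1e-6).
Plain Langevin steps contribute the same diagonal factor; this term is not
optional — without it the flow density does not integrate to 1.

Inversion uses a one-step surrogate: the gradient-free preimage

    t = (z_B − T(x_A)) ⊙ exp(−S(x_A)) − ε·exp(σ(x_A))

is plugged into `∇U` once, giving `x_B ≈ t + (ε²/2) ∇U((x_A, t))_B` and the
inverse logdet term `Σ_i [−S_i + ln|1 + (ε²/2) H_ii(t)|]`.  The
reconstruction error is O(ε²) per step (empirically: halving ε shrinks the
round-trip error by ≥3×), so forward and inverse log-determinants agree only
to O(ε²).

## Training

The loss is the mean squared log-density ratio over the flow's own draws,

    L(θ) = E_{π_u}[(ln γ + ln π_u(x) − ln p_unnorm(x))²],

which is nonnegative on every batch (the raw Monte-Carlo KL estimate is
not), and reduces to the normalized squared-KL loss when the scale `γ`
equals the normalizer `Z`.  `γ` is taken from the target when `Z` is known,
or estimated once before training by importance sampling
`γ̂ = (1/n) Σ p_unnorm(x_i)/q(x_i)`, `x_i ∼ q` (standard Monte-Carlo rate,
slope −½ of log-error in log-n).

For its own samples the flow's log-density is accumulated along the forward
pass, `ln π_u(f(x₀)) = ln q(x₀) − Σ fwd logdet`, which is exactly
differentiable; the inverse-pass density (used when scoring external
points) differs by the surrogate's O(ε²) error.  Gradients are fully
pathwise: reverse-mode differentiation through the conditioner networks,
the drift (needing Hessian-vector products of `U`), and the log-determinant
(needing third derivatives of `U`, obtained by a batched central finite
difference of the Hessian diagonal; gradient checks pass at 1e-3 relative
against full finite differences of the loss).

Numerical safeguards: raw `σ` and `S` outputs are soft-clamped to
`c·tanh(raw/c)` (c = 5 and 8) before exponentiation, and the global
gradient norm is clipped at 100 (configurable).  Both are inactive in a
well-behaved run (the clamp has unit slope at 0) but prevent overflow
during early training on multimodal targets.  A vanishing diagonal factor
`|1 − (ε²/2)H_ii| < 1e-12` raises an error advising a smaller ε — this also
sets the admissible ε for stiff targets: `ε < √(2/max H_ii)` (e.g. the
strongly correlated Gaussian with largest precision eigenvalue 100 requires
ε ≲ 0.14).

For energies with superlinear gradients (the quartic ring tails), the
explicit drift step is unstable beyond a finite radius: one overshoot and
subsequent drift steps amplify without bound — the same pathology that
motivates tamed Euler–Maruyama schemes for such SDEs.  The drift
displacement `(ε²/2)∇U` is therefore capped elementwise at 5.0, orders of
magnitude beyond any within-support displacement; capped coordinates
contribute no drift derivative, and the log-determinant and reverse-mode
pass account for that consistently.  Learning-rate warmup (linear, then
cosine decay) is used on the ring family, where early batches carry very
large squared log-ratios.

The scale `γ` is estimated once before training with n = batch-size base
draws by default.  When the normalizer is extremely small (a Bayesian
posterior's evidence, e.g. ~e^(−260) for a 500-row logistic regression),
the one-batch estimate of ln γ carries several nats of noise, which the
quadratic loss converts into a systematic dispersion bias; passing a fixed
`gamma` obtained from a larger importance sample (2×10⁴ draws gives ±0.5
nats there) removes it.

Two documented profiles: the full-scale profile (8 layers, 3×512-unit
conditioners, batch 8000, 10 000 plain-gradient iterations at rate 0.05)
and a reduced test profile (4 layers, 2×64 units, batch 1024,
1500–3000 Adam iterations at rate 5e-3 with cosine decay) that trains each
2-D benchmark in minutes on one CPU.  Adam plus cosine decay is the
practical default at reduced scale: plain gradient descent at a fixed rate
is markedly less stable through the early, large-loss phase.

### Choice of ε and Ls per target

The drift strength `(ε²/2)·Ls·2T` sets how far the *initial* (zero-network)
flow transports base mass toward the target's modes.  On well-separated
mixtures this matters: with a weak drift the initial map is unimodal and
gradient descent readily collapses onto a single mode (a barrier separates
the collapsed and mass-split optima); with `ε = 0.4, Ls = 5` the initial
map is already bimodal and training only has to move the basin boundary, a
continuous path the optimizer can follow.  One further initialization
choice matters here: at `σ = 0` every half-update adds the systematic
offset `+ε` per Langevin step (`Ls·ε` per half-update), which at a strong
drift setting swamps the drift's structure.  The mixture experiments
therefore initialize the σ nets' final bias at −2 (`sigma_init` in the
config), damping the pseudo-noise to `ε·e^{−2}` at the start; σ remains
fully learnable.  Default elsewhere is 0.  On stiff Gaussians ε is bounded
by the singularity condition above, and the drift is of secondary value;
`ε = 0.05, Ls = 2` is the default there.  These per-target settings live in
`nflmc.experiments`.

## Synthetic data and what passing tests show

The logistic-regression generator draws standardized standard-normal
features and Bernoulli labels through a sigmoid in a known weight vector —
matching the scale conventions of small tabular benchmarks (hundreds of
rows, 3–25 features, standardized columns) but with independent, Gaussian,
noise-free features.  Real tables have correlated, discrete and heavier-
tailed columns; passing the synthetic posterior checks demonstrates correct
posterior geometry handling, not benchmark-grade classification accuracy.

## Diagnostics

Effective sample size uses the truncated formula `ESS = N/(1 + 2 Σ_{s≤M}
ρ(s))` with `M = 30`, per dimension, with the stationary single-mean ACF
estimator; nonpositive denominators (possible with negative ACF sums) are
floored at 1e-3 and flagged.  MMD² is the biased V-statistic with a
Gaussian kernel; the bandwidth defaults to the median pooled pairwise
distance and is overridable.  The mode-weight audit assigns each sample to
the nearer of two centers (ties to the first).

## Known limitations

- The inverse is approximate; densities of *external* points degrade as
  ε grows, and `flow_log_prob` normalization holds to ~1e-2 only for
  ε ≲ 0.05 at the tested depths.
- Off-diagonal within-block curvature is ignored in the log-determinant; on
  strongly rotation-coupled targets the reported density is approximate
  even at the forward pass (training remains consistent because the same
  approximation defines the optimized objective).
- Mode-weight recovery on well-separated mixtures is the stress case for
  the reduced profile.  A weak drift lets the optimizer collapse the flow
  onto a single mode (an absorbing state of the squared loss); a drift
  strong enough to hold the split (`ε = 0.4, Ls = 5`) warps the base so
  heavily that four affine corrections cannot fully restore unit cluster
  covariance, leaving a residual loss (~0.4) under which the recovered
  dominant-mode mass scatters several percentage points around its true
  value across seeds.  The full-scale profile's depth (8 layers, 3×512
  conditioners) is what resolves this tension.  At reduced scale the
  package ships two mitigations: the drift-dominated initialization above,
  and a restart rule (`nflmc.experiments`) that retrains when fewer than 1%
  of draws land in one basin — a coverage check, deliberately blind to the
  mode weights being measured.  The mode-weight diagnostic should accompany
  any multimodal run.
- Targets must have D ≥ 2 (coupling needs two blocks) and finite energy on
  all finite points.
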