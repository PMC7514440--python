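"""Coupling-layer properties: identity reduction, invertibility order,
log-determinant oracles, triangular structure, density normalization."""

import numpy as np
import pytest

from nflmc.flow import (FlowSingularityError, build_flow,
                        flow_log_prob, forward_layer, inverse_layer,
                        langevin_half_step, sample_flow)
from nflmc.targets import gaussian_target

from conftest import perturb_conditioners

SCALE_ATANH = lambda s, cap: cap * np.arctanh(s / cap)  # noqa: E731


def set_constant_output(net, value):
    """Force an MLP to output a constant by zeroing weights, setting last bias."""
    for w in net.W:
        w[...] = 0.0
    for b in net.b:
        b[...] = 0.0
    net.b[-1][...] = value


def affine_stack(target, s=0.0, t=0.0, num_layers=1, **kw):
    """eps=0 stack whose S and T conditioners output constants (sigma 0)."""
    from nflmc.flow import SCALE_CAP
    stack = build_flow(target, num_layers=num_layers, hidden=(4,), epsilon=0.0,
                       langevin_steps=1, seed=0, **kw)
    raw_s = SCALE_ATANH(s, SCALE_CAP)
    for layer in stack.layers:
        for cond in (layer.conditioners_first, layer.conditioners_second):
            set_constant_output(cond.scale, raw_s)
            set_constant_output(cond.shift, t)
            set_constant_output(cond.sigma, 0.0)
    return stack


class TestIdentityReduction:
    def test_eps_zero_zero_conditioners_is_identity(self, std_normal_2d, rng):
        stack = build_flow(std_normal_2d, num_layers=3, hidden=(8,),
                           epsilon=0.0, langevin_steps=2, seed=1)
        x = rng.normal(0, 2, (50, 2))
        z, ld = stack.forward(x)
        assert np.array_equal(z, x)
        assert np.array_equal(ld, np.zeros(50))
        xr, ldi = stack.inverse(x)
        assert np.array_equal(xr, x)
        assert np.array_equal(ldi, np.zeros(50))

    def test_eps_zero_half_step_is_identity(self, std_normal_2d, rng):
        stack = build_flow(std_normal_2d, num_layers=1, epsilon=0.0, seed=0)
        x = rng.normal(size=2)
        assert np.array_equal(langevin_half_step(x, "second", stack.layers[0]), x)


class TestLangevinHalfStep:
    def test_quadratic_hand_arithmetic(self, std_normal_2d):
        # U = ||x||^2/2, x=(1,2), eps=0.1, sigma=0:
        # second coord -> 2 - (0.01/2)*2 + 0.1*exp(0) = 2.09
        stack = build_flow(std_normal_2d, num_layers=1, hidden=(4,),
                           epsilon=0.1, langevin_steps=1, seed=0)
        out = langevin_half_step(np.array([1.0, 2.0]), "second", stack.layers[0])
        assert out[1] == pytest.approx(2.09)

    def test_complementary_block_unchanged(self, std_normal_2d, rng):
        stack = build_flow(std_normal_2d, num_layers=1, hidden=(4,),
                           epsilon=0.1, langevin_steps=1, seed=0)
        perturb_conditioners(stack)
        x = rng.normal(size=2)
        out = langevin_half_step(x, "second", stack.layers[0])
        assert out[0] == x[0]


class TestAffineExactness:
    def test_constant_scale_logdet(self, std_normal_2d, rng):
        # pure affine coupling with S=s, T=0: logdet = s*D per layer
        s = 0.3
        stack = affine_stack(std_normal_2d, s=s)
        x = rng.normal(0, 1, (20, 2))
        _, ld = stack.forward(x)
        assert np.allclose(ld, s * 2)

    def test_affine_inverse_is_exact(self, std_normal_2d, rng):
        stack = affine_stack(std_normal_2d, s=0.4, t=0.7, num_layers=2)
        x = rng.normal(0, 1, (30, 2))
        z, ldf = stack.forward(x)
        xr, ldi = stack.inverse(z)
        assert np.allclose(xr, x, atol=1e-10)
        assert np.allclose(ldf + ldi, 0.0, atol=1e-10)

    def test_affine_pushforward_log_density(self, std_normal_2d, rng):
        # single eps=0 layer, constant S=s, T=t: closed-form change of variables
        s, t = 0.25, -0.5
        stack = affine_stack(std_normal_2d, s=s, t=t)
        z = rng.normal(0, 1, (40, 2))
        x = (z - t) * np.exp(-s)
        expected = stack.base.log_prob(x) - 2 * s
        assert np.allclose(stack.log_prob(z), expected, atol=1e-10)


class TestRoundTrip:
    def test_inversion_error_order_in_eps(self, std_normal_2d, rng):
        """Reconstruction error is O(eps^2): halving eps shrinks it >= 3x."""
        x = rng.normal(0, 1, (100, 2))
        errs = []
        for eps in (0.1, 0.05, 0.025):
            stack = build_flow(std_normal_2d, num_layers=2, hidden=(8, 8),
                               epsilon=eps, langevin_steps=2, seed=4)
            perturb_conditioners(stack, scale=0.05)
            z, _ = stack.forward(x)
            xr, _ = stack.inverse(z)
            errs.append(np.max(np.linalg.norm(xr - x, axis=1)))
        assert errs[0] / errs[1] >= 3.0
        assert errs[1] / errs[2] >= 3.0

    def test_forward_inverse_logdets_agree_to_eps_sq(self, small_stack, rng):
        x = rng.normal(0, 1, (50, 2))
        z, ldf = small_stack.forward(x)
        _, ldi = small_stack.inverse(z)
        assert np.max(np.abs(ldf + ldi)) < 10 * small_stack.layers[0].epsilon ** 2


class TestJacobianOracle:
    @pytest.mark.parametrize("eps,ls", [(0.1, 1), (0.08, 3)])
    def test_fwd_logdet_matches_full_jacobian(self, eps, ls, rng):
        """Diagonal-Hessian target: accumulated logdet equals ln|det J|."""
        target = gaussian_target(np.zeros(2), np.diag([1.0, 4.0]))
        stack = build_flow(target, num_layers=2, hidden=(8,), epsilon=eps,
                           langevin_steps=ls, seed=5)
        perturb_conditioners(stack, scale=0.1)
        x = rng.normal(0, 1, 2)
        h = 1e-6
        jac = np.zeros((2, 2))
        for j in range(2):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            jac[:, j] = (stack.forward(xp[None])[0][0]
                         - stack.forward(xm[None])[0][0]) / (2 * h)
        _, ld = stack.forward(x[None])
        assert ld[0] == pytest.approx(np.log(abs(np.linalg.det(jac))), abs=1e-6)

    def test_fused_inverse_logdet_identity_hessian(self):
        """S=0, U=||x||^2/2: per-coordinate inverse term is ln(1 + eps^2/2)."""
        target = gaussian_target(np.zeros(2), np.eye(2))
        eps = 0.2
        stack = build_flow(target, num_layers=1, hidden=(4,), epsilon=eps,
                           langevin_steps=1, seed=0)
        z = np.array([0.4, -1.1])
        _, ldi = stack.layers[0].inverse(z[None])
        assert ldi[0] == pytest.approx(2 * np.log(1 + eps**2 / 2), rel=1e-12)


class TestTriangularStructure:
    def test_half_updates_touch_only_their_block(self, std_normal_2d, rng):
        stack = build_flow(std_normal_2d, num_layers=1, hidden=(8,),
                           epsilon=0.1, langevin_steps=2, seed=2)
        perturb_conditioners(stack)
        layer = stack.layers[0]
        x = rng.normal(0, 1, (10, 2))
        (idx1, cond1_idx, c1), (idx2, _, c2) = layer._halves()
        y, _ = layer._half_forward(x, idx1, cond1_idx, c1, None)
        assert np.array_equal(y[:, cond1_idx], x[:, cond1_idx])
        z, _ = layer._half_forward(y, idx2, idx1, c2, None)
        assert np.array_equal(z[:, idx1], y[:, idx1])


class TestFlowLogProb:
    def test_identity_stack_equals_base(self, std_normal_2d, rng):
        stack = build_flow(std_normal_2d, num_layers=2, epsilon=0.0, seed=0)
        z = rng.normal(0, 1, (30, 2))
        assert np.allclose(stack.log_prob(z), stack.base.log_prob(z))

    def test_single_point_wrapper(self, small_stack):
        z = np.array([0.3, -0.2])
        assert flow_log_prob(z, small_stack) == pytest.approx(
            small_stack.log_prob(z[None])[0])

    def test_density_normalization_by_quadrature(self, small_stack):
        """2-D quadrature of exp(log_prob) integrates to 1 within 2e-2."""
        g = np.linspace(-7, 7, 301)
        xx, yy = np.meshgrid(g, g, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        dens = np.exp(small_stack.log_prob(pts)).reshape(xx.shape)
        mass = np.trapezoid(np.trapezoid(dens, g, axis=1), g)
        assert mass == pytest.approx(1.0, abs=2e-2)


class TestSampling:
    def test_identity_stack_returns_base_draws(self, std_normal_2d):
        stack = build_flow(std_normal_2d, num_layers=1, epsilon=0.0, seed=0)
        batch = sample_flow(stack, 100, seed=11)
        rng = np.random.default_rng(11)
        assert np.array_equal(batch.points, stack.base.sample(100, rng))

    def test_same_seed_is_bitwise_identical(self, small_stack):
        b1 = sample_flow(small_stack, 50, seed=42)
        b2 = sample_flow(small_stack, 50, seed=42)
        assert np.array_equal(b1.points, b2.points)
        assert np.array_equal(b1.log_q_flow, b2.log_q_flow)

    def test_identity_stack_clt_mean(self, std_normal_2d):
        stack = build_flow(std_normal_2d, num_layers=1, epsilon=0.0, seed=0)
        n = 100_000
        batch = sample_flow(stack, n, seed=3)
        assert np.all(np.abs(batch.points.mean(axis=0)) < 3 / np.sqrt(n))

    def test_batch_fields_populated(self, small_stack):
        batch = sample_flow(small_stack, 20, seed=0)
        t = small_stack.target
        assert np.allclose(batch.log_target_unnorm, -t.energy(batch.points))
        assert np.allclose(batch.log_q_flow, small_stack.log_prob(batch.points))


class TestValidation:
    def test_one_dimensional_targets_rejected(self):
        t = gaussian_target(np.zeros(1), np.eye(1))
        with pytest.raises(ValueError, match="dimension >= 2"):
            build_flow(t, num_layers=1)

    def test_singular_jacobian_factor_raises(self):
        # 1 - (eps^2/2) H_ii == 0 when H = 2/eps^2
        eps = 1.0
        target = gaussian_target(np.zeros(2), np.diag([eps**2 / 2, eps**2 / 2]))
        stack = build_flow(target, num_layers=1, hidden=(4,), epsilon=eps,
                           langevin_steps=1, seed=0)
        with pytest.raises(FlowSingularityError, match="smaller step"):
            stack.forward(np.zeros((1, 2)))

    def test_functional_wrappers_round_trip(self, small_stack, rng):
        layer = small_stack.layers[0]
        x = rng.normal(size=2)
        z, ldf = forward_layer(x, layer)
        xr, ldi = inverse_layer(z, layer)
        assert np.allclose(xr, x, atol=1e-3)
        assert ldf == pytest.approx(-ldi, abs=1e-3)
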