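"""Losses, gamma estimation, pathwise gradients, and the training loop."""

import numpy as np
import pytest

from nflmc.flow import BaseDistribution, SampleBatch, build_flow
from nflmc.targets import gaussian_target, make_target
from nflmc.training import (TrainConfig, estimate_gamma, loss_and_grad,
                            squared_kl_loss, train_nflmc, unnormalized_loss)

from conftest import perturb_conditioners


def batch_from(points, log_q, log_p):
    return SampleBatch(points=points, log_q_flow=log_q, log_target_unnorm=log_p)


class TestSquaredKLLoss:
    def test_zero_when_flow_equals_target(self, rng):
        pts = rng.standard_normal((100, 2))
        lp = -0.5 * np.sum(pts**2, axis=1) - np.log(2 * np.pi)
        assert squared_kl_loss(batch_from(pts, lp, lp)) == 0.0

    def test_gaussian_mean_shift_population_value(self, rng):
        # draws from N(0,1) scored against N(1,1): E[(m x - m^2/2)^2]... the
        # log-ratio is x - 1/2 so E[(x - 1/2)^2] = 1 + 1/4 = m^4/4 + m^2 at m=1
        n = 200_000
        x = rng.standard_normal(n)
        log_q = -0.5 * x**2
        log_p = -0.5 * (x - 1.0) ** 2
        loss = squared_kl_loss(batch_from(x[:, None], log_q, log_p))
        sd = np.std((log_q - log_p) ** 2) / np.sqrt(n)
        assert abs(loss - 1.25) < 3 * sd

    def test_loss_dominates_squared_mean_log_ratio(self, rng):
        # Jensen: E[r^2] >= (E r)^2 on any batch
        r = rng.normal(0.3, 1.0, 500)
        loss = squared_kl_loss(batch_from(np.zeros((500, 1)), r, np.zeros(500)))
        assert loss >= np.mean(r) ** 2

    def test_nonnegative(self, rng):
        b = batch_from(np.zeros((50, 1)), rng.normal(size=50), rng.normal(size=50))
        assert squared_kl_loss(b) >= 0


class TestUnnormalizedLoss:
    def test_recovers_normalized_loss_at_gamma_z(self, rng):
        pts = np.zeros((100, 1))
        log_q = rng.normal(size=100)
        log_pi = rng.normal(size=100)
        z = 3.7
        norm = batch_from(pts, log_q, log_pi)
        unnorm = batch_from(pts, log_q, log_pi + np.log(z))
        assert unnormalized_loss(unnorm, gamma=z) == pytest.approx(
            squared_kl_loss(norm))

    def test_constant_ratio_hand_value(self):
        # pi_u == pi_t exactly, p_unnorm = 2 pi_t, gamma = 1 -> (ln 2)^2
        lp = np.full(50, -1.3)
        b = batch_from(np.zeros((50, 1)), lp, lp + np.log(2.0))
        assert unnormalized_loss(b, 1.0) == pytest.approx(np.log(2.0) ** 2)

    def test_minimized_at_gamma_equal_z(self, rng):
        lp = rng.normal(size=200)
        z = 2.5
        b = batch_from(np.zeros((200, 1)), lp, lp + np.log(z))
        losses = {g: unnormalized_loss(b, g) for g in (z / 2, z, z * 2)}
        assert losses[z] < losses[z / 2] and losses[z] < losses[z * 2]

    def test_rejects_nonpositive_gamma(self):
        b = batch_from(np.zeros((2, 1)), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            unnormalized_loss(b, 0.0)


class TestGammaEstimator:
    def test_identical_densities_give_one(self):
        t = gaussian_target(np.zeros(2), np.eye(2))
        # p_unnorm = exp(-U) with U of N(0,I) is (2pi)^... include normalizer:
        base = BaseDistribution(np.zeros(2), np.ones(2))
        est = estimate_gamma(t, base, n=100, seed=0)
        assert est == pytest.approx(np.exp(t.log_norm_const))

    def test_known_gaussian_normalizer(self):
        # p_unnorm(x) = exp(-x.x/2) in 1-D... use 2-D: Z = 2*pi
        t = gaussian_target(np.zeros(2), np.eye(2))
        base = BaseDistribution(np.zeros(2), 1.5 * np.ones(2))
        est = estimate_gamma(t, base, n=100_000, seed=1)
        assert est == pytest.approx(2 * np.pi, rel=0.02)

    def test_monte_carlo_rate(self):
        """log-error vs log-n slope is about -1/2."""
        t = gaussian_target(np.zeros(2), np.eye(2))
        base = BaseDistribution(np.zeros(2), 1.5 * np.ones(2))
        z = 2 * np.pi
        ns = [100, 1000, 10_000, 100_000]
        errs = []
        for n in ns:
            reps = [abs(estimate_gamma(t, base, n, seed=s) - z)
                    for s in range(5)]
            errs.append(np.mean(reps))
        slope = np.polyfit(np.log(ns), np.log(errs), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)


class TestLossGradient:
    def test_zero_at_exact_fit(self):
        t = gaussian_target(np.zeros(2), np.eye(2))
        stack = build_flow(t, num_layers=2, hidden=(6,), epsilon=0.0,
                           langevin_steps=1, seed=0)
        x0 = stack.base.sample(64, np.random.default_rng(0))
        loss, grads = loss_and_grad(stack, x0, np.exp(t.log_norm_const))
        assert loss == pytest.approx(0.0, abs=1e-20)
        assert all(np.allclose(g, 0.0) for g in grads)

    @pytest.mark.parametrize("target_name,eps", [("mog1", 0.08), ("ring", 0.05)])
    def test_matches_finite_differences(self, target_name, eps):
        """Full-parameter FD check on a miniature stack, relative 1e-3."""
        t = make_target(target_name)
        stack = build_flow(t, num_layers=2, hidden=(4,), epsilon=eps,
                           langevin_steps=2, seed=11)
        perturb_conditioners(stack, scale=0.1, seed=13)
        x0 = stack.base.sample(16, np.random.default_rng(17))
        gamma = 1.0 if t.log_norm_const == 0.0 else 2.0
        loss, grads = loss_and_grad(stack, x0, gamma)
        rng = np.random.default_rng(19)
        params = stack.params
        checked = 0
        for pi, p in enumerate(params):
            flat = p.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size),
                                  replace=False):
                old = flat[idx]
                flat[idx] = old + 1e-6
                lp, _ = loss_and_grad(stack, x0, gamma)
                flat[idx] = old - 1e-6
                lm, _ = loss_and_grad(stack, x0, gamma)
                flat[idx] = old
                fd = (lp - lm) / 2e-6
                an = grads[pi].reshape(-1)[idx]
                assert an == pytest.approx(fd, rel=1e-3, abs=1e-7)
                checked += 1
        assert checked > 20


class TestTrainingLoop:
    def test_exact_fit_stays_near_zero(self):
        # plain gradient descent: zero loss is a fixed point (Adam is
        # scale-free and would amplify float-residual gradients)
        t = gaussian_target(np.zeros(2), np.eye(2))
        config = TrainConfig(iterations=20, batch_size=64, epsilon=0.0,
                             num_layers=2, hidden=(4,), seed=0,
                             optimizer="sgd")
        state = train_nflmc(t, config=config)
        assert max(state.loss_trace) < 1e-10

    def test_loss_trace_nonnegative_and_reproducible(self):
        t = make_target("mog1")
        config = TrainConfig(iterations=30, batch_size=128, epsilon=0.05,
                             num_layers=2, hidden=(8,), seed=5)
        s1 = train_nflmc(t, config=config)
        s2 = train_nflmc(t, config=config)
        assert all(v >= 0 for v in s1.loss_trace)
        assert s1.loss_trace == s2.loss_trace

    def test_moment_recovery_shifted_gaussian(self):
        """Flow trained toward N((3,3), I) from N(0, I) recovers the mean."""
        t = gaussian_target(np.array([3.0, 3.0]), np.eye(2))
        config = TrainConfig(iterations=400, batch_size=256, epsilon=0.05,
                             langevin_steps=2, num_layers=3, hidden=(16, 16),
                             learning_rate=0.01, seed=7)
        state = train_nflmc(t, config=config)
        draws = state.stack.sample(4000, seed=70).points
        assert np.all(np.abs(draws.mean(axis=0) - 3.0) < 0.15)

    def test_gamma_estimate_path(self):
        t = make_target("ring")  # unknown normalizer
        config = TrainConfig(iterations=5, batch_size=128, epsilon=0.05,
                             num_layers=2, hidden=(4,), gamma="estimate",
                             seed=1)
        state = train_nflmc(t, config=config)
        assert state.gamma > 0

    def test_unknown_normalizer_without_gamma_raises(self):
        t = make_target("ring")
        with pytest.raises(ValueError, match="gamma"):
            train_nflmc(t, config=TrainConfig(iterations=1, batch_size=8,
                                              num_layers=2, hidden=(4,)))


class TestTrainConfig:
    @pytest.mark.parametrize("field,value", [
        ("learning_rate", -0.1), ("iterations", 0), ("batch_size", 0),
        ("gamma", -1.0), ("optimizer", "sgdm"), ("gamma", "guess"),
    ])
    def test_validation(self, field, value):
        with pytest.raises(ValueError):
            TrainConfig(**{field: value})

    def test_profiles(self):
        assert TrainConfig.full_profile().num_layers == 8
        assert TrainConfig.full_profile().batch_size == 8000
        assert TrainConfig.test_profile().num_layers == 4
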