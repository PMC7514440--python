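import numpy as np
import pytest

from nflmc.flow import build_flow
from nflmc.targets import gaussian_target


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def std_normal_2d():
    return gaussian_target(np.zeros(2), np.eye(2), name="n01")


def perturb_conditioners(stack, scale=0.1, seed=7):
    """Randomize conditioner weights so a stack is not the identity map."""
    rr = np.random.default_rng(seed)
    for net in stack.conditioner_nets:
        for p in net.params:
            p += rr.normal(0.0, scale, p.shape)
    return stack


@pytest.fixture
def small_stack(std_normal_2d):
    """A 2-layer non-trivial stack on the standard normal target."""
    stack = build_flow(std_normal_2d, num_layers=2, hidden=(8, 8),
                       epsilon=0.05, langevin_steps=2, seed=3)
    return perturb_conditioners(stack)
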