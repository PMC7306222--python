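import numpy as np
import pytest

from hookmorph import HookShapeParams, Outline, generate_hook


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def unit_circle():
    t = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    return Outline(np.column_stack([np.cos(t), np.sin(t)]))


@pytest.fixture(scope="session")
def ellipse_2x1():
    t = np.linspace(0.0, 2.0 * np.pi, 512, endpoint=False)
    return Outline(np.column_stack([2.0 * np.cos(t), np.sin(t)]))


@pytest.fixture(scope="session")
def default_hook():
    return generate_hook(HookShapeParams())


@pytest.fixture(scope="session")
def hook_family():
    """Ten noiseless hooks spanning the curvature/thickness ranges."""
    rng = np.random.default_rng(7)
    hooks = []
    for _ in range(10):
        p = HookShapeParams(
            kappa=rng.uniform(0.6, 2.4),
            tau=rng.uniform(0.18, 0.42),
            taper=rng.uniform(1.0, 2.5),
        )
        hooks.append(generate_hook(p))
    return hooks
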