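import numpy as np
import pytest

from latentlink import SynthConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """One planted-LV study small enough for fast resampling tests."""
    cfg = SynthConfig(n_participants=400, n_brain=10, n_behavior=5, n_latent=1,
                      effect_sizes=(0.6,), seed=7)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def gaussian_study():
    """Continuous-behavior study for Pearson-path identities."""
    cfg = SynthConfig(n_participants=400, n_brain=8, n_behavior=5, n_latent=2,
                      effect_sizes=(0.5, 0.3), behavior_family="gaussian",
                      seed=11)
    return generate_study(cfg)


def random_cross_products(rng, n=300, p=8, q=5, kind="pearson"):
    """Cross-products of pure-noise blocks, for spectrum/decomposition tests."""
    from latentlink import build_cross_products
    X = rng.normal(size=(n, p))
    Y = rng.normal(size=(n, q))
    return build_cross_products(X, Y, kind)
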