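import pytest

from bfirt.inference import SamplerConfig, fit
from bfirt.models import ModelSpec, ModelVariant
from bfirt.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but information-rich simulated dataset (N=150, m=9, 3 dims)."""
    cfg = SimConfig(N=150, m=9, n_specific=3, seed=20, rho_general=-0.4)
    U, T, truth = simulate_dataset(cfg)
    return cfg, U, T, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short BFHM fit of the small dataset, shared across tests."""
    cfg, U, T, truth = small_dataset
    return fit(U, T, cfg.pattern, ModelSpec(ModelVariant.BFHM),
               sampler=SamplerConfig(chains=2, iterations=1200, thin=1, seed=9))


@pytest.fixture(scope="session")
def tiny_other_fit():
    """A fit on a differently sized dataset (for incomparability checks)."""
    cfg = SimConfig(N=60, m=6, n_specific=3, seed=21)
    U, T, _ = simulate_dataset(cfg)
    return fit(U, T, cfg.pattern, ModelSpec(ModelVariant.BFHM),
               sampler=SamplerConfig(chains=2, iterations=400, thin=1, seed=2))


@pytest.fixture(scope="session")
def small_fit_cmhm(small_dataset):
    cfg, U, T, truth = small_dataset
    return fit(U, T, cfg.pattern, ModelSpec(ModelVariant.CMHM),
               sampler=SamplerConfig(chains=2, iterations=1000, thin=1, seed=9))
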