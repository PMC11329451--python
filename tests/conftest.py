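import numpy as np
import pytest

from urbanscale import synthetic


@pytest.fixture(scope="session")
def city_ensemble():
    """Standard synthetic ensemble: 50,000 Zipf cities with conditional
    power-law emissions (beta=0.81, 0.5 decades of scatter)."""
    cfg = synthetic.CityGenConfig(
        n_cities=50_000,
        pop_min=1_000,
        zipf_exponent=2.0,
        beta_true=0.81,
        prefactor_A=1.0,
        log_scatter_sigma=0.5,
        seed=7,
    )
    pops = synthetic.generate_populations(cfg)
    emissions = synthetic.generate_conditional_measure(
        pops, cfg.beta_true, cfg.prefactor_A, cfg.log_scatter_sigma, cfg.seed, "e_co2"
    )
    return cfg, pops, emissions


@pytest.fixture(scope="session")
def cascade_grid():
    """Deterministic multiplicative cascade, weights (0.4, 0.3, 0.2, 0.1)."""
    cfg = synthetic.CascadeConfig(depth=8, weights=(0.4, 0.3, 0.2, 0.1))
    return cfg, synthetic.generate_cascade(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
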