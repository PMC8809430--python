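import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160901)


@pytest.fixture
def small_dataset():
    """A small single-species simulated survey (4 sites x 8 months)."""
    from vulturesurvey.synthetic import SimParams, SpeciesSimParams, simulate_counts

    params = SimParams(
        n_sites=4,
        n_months=8,
        species={
            "White-rumped Vulture": SpeciesSimParams(initial_logN=np.log([8.0, 12, 20, 30]))
        },
        seed=11,
    )
    dataset, truth = simulate_counts(params)
    return dataset, truth


@pytest.fixture
def tiny_mcmc_config():
    """Very short schedule for structural (non-inferential) MCMC tests."""
    from vulturesurvey.mcmc import MCMCConfig

    return MCMCConfig(
        n_chains=2, n_iterations=600, n_burnin=300, n_adapt=200, thin=5, seed=5
    )


@pytest.fixture
def fitted_draws(small_dataset, tiny_mcmc_config):
    from vulturesurvey.mcmc import run_mcmc

    dataset, _ = small_dataset
    return run_mcmc(dataset, config=tiny_mcmc_config)
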