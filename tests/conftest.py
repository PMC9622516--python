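import numpy as np
import pytest

from effort_ddm.hierarchical import McmcConfig, fit_hierarchical
from effort_ddm.simulate import (
    build_design,
    sample_population,
    simulate_study,
    reference_population,
)


def recovery_seeds(seed: int):
    """Sub-seeds for design, population, simulation and fit, derived the
    same way as in scripts/acceptance.py."""
    ss = np.random.SeedSequence(seed)
    return tuple(int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))


@pytest.fixture(scope="session")
def small_study():
    """A 6-participant synthetic study from the default population."""
    design = build_design(6, seed=11)
    truth = sample_population(reference_population(), 6, seed=12)
    trials = simulate_study(truth, design, seed=13)
    return design, truth, trials


@pytest.fixture(scope="session")
def recovery_study():
    """The parameter-recovery setting: 20 diffusion agents at the
    reference group means (boundary 2.09, bias 0.52, non-decision 0.66,
    reward 0.22, effort 0.12, theta bias shift 0.03; SDs 10% of means),
    180 titrated decisions each. Seeds are derived exactly as the
    acceptance script derives them from its --seed argument."""
    s_design, s_pop, s_sim, _ = recovery_seeds(1)
    design = build_design(20, seed=s_design)
    truth = sample_population(reference_population(), 20, seed=s_pop)
    trials = simulate_study(truth, design, seed=s_sim)
    return truth, trials


@pytest.fixture(scope="session")
def recovery_fit(recovery_study):
    """Hierarchical attribute-model fit of the recovery study at the
    default reduced budget; shared by the recovery and posterior
    predictive checks. The clean synthetic data are fit in full (the RT
    trim is an outlier guard for empirical data)."""
    _, trials = recovery_study
    _, _, _, s_fit = recovery_seeds(1)
    return fit_hierarchical(
        trials, "attribute", McmcConfig(n_chains=4, n_draws=2000, n_burn=3000, seed=s_fit)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
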