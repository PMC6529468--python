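import numpy as np
import pandas as pd
import pytest

from pulsen15.quantify import quantify_experiment
from pulsen15.simulate import GeneratorConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One seeded synthetic head-tissue experiment at study-default
    conditions (500 proteins, noise 0.1, purity 0.995, ub bias 3.72)."""
    cfg = GeneratorConfig(n_proteins=500, rng_seed=11, ub_old_bias_beta=3.72)
    proteome, psms, xics = simulate_experiment(cfg)
    return cfg, proteome, psms, xics


@pytest.fixture(scope="session")
def default_turnover(default_experiment):
    """Protein turnover table quantified from the default experiment."""
    cfg, proteome, psms, xics = default_experiment
    total = quantify_experiment(psms, xics, mode="total")
    return total


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Noise-free, fully pure variant: the chain must invert exactly."""
    cfg = GeneratorConfig(n_proteins=60, rng_seed=3, noise_sigma=0.0,
                          label_purity=1.0)
    proteome, psms, xics = simulate_experiment(cfg)
    return cfg, proteome, psms, xics
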