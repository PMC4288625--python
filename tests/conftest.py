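import warnings

import numpy as np
import pytest

from bprsig import McmcConfig, SyntheticConfig, generate_cohort

# slow-mixing warnings from near-separated LOOCV folds are expected noise here
warnings.filterwarnings("ignore", message="probit Gibbs chain may not have converged")


@pytest.fixture(scope="session")
def fast_mcmc():
    return McmcConfig(iterations=2000, burn_in=500)


@pytest.fixture(scope="session")
def signal_cohort():
    """Small strong-signal cohort: 300 genes, 24 IPF / 16 normal, 10% DE at 1.5 sd."""
    config = SyntheticConfig(seed=20140902, n_features=300, n_ipf=24, n_normal=16,
                             de_fraction=0.10, effect_size_sd=1.5)
    matrix, annotations, truth = generate_cohort(config)
    labels = np.array([a.label for a in annotations])
    return matrix, annotations, labels, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no differential expression at all."""
    config = SyntheticConfig(seed=77, n_features=300, n_ipf=20, n_normal=20,
                             de_fraction=0.10, effect_size_sd=0.0)
    matrix, annotations, truth = generate_cohort(config)
    labels = np.array([a.label for a in annotations])
    return matrix, annotations, labels, truth
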