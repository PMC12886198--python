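"""Shared fixtures.

The replicated simulation studies are expensive (each replication trains a
network inside the profiling loop), so they are session-scoped and shared by
the acceptance tests that look at different aspects of the same study.
"""

import numpy as np
import pytest

from cpcox.evaluation import replicate_experiment
from cpcox.model import FitConfig
from cpcox.simulate import SimConfig, sample_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest Case-1 dataset with the truth block retained."""
    return sample_dataset(SimConfig(n=400, case_id=1, seed=42))


@pytest.fixture(scope="session")
def case1_study_n1000():
    """Case 1, n=1000, 40 replications of the deep change-point fit.

    The first 20 replications are an exact M=20 study (seeds base+1..20);
    the full 40 stabilize the threshold's sampling-error estimate.
    """
    return replicate_experiment(1, 1000, 40, FitConfig(), base_seed=1000,
                                kind="deep-cp")


@pytest.fixture(scope="session")
def case1_study_n2000():
    """Same seeds at n=2000, pairing replications with the n=1000 study."""
    return replicate_experiment(1, 2000, 40, FitConfig(), base_seed=1000,
                                kind="deep-cp")


@pytest.fixture(scope="session")
def case1_re_n4000():
    """n=4000 arm (10 paired seeds) for the relative-error trend."""
    return replicate_experiment(1, 4000, 10, FitConfig(), base_seed=1000,
                                kind="deep-cp")
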