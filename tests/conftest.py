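import numpy as np
import pytest

from pcassay import load_table1_fixture, load_table2_fixture
from pcassay.synthetic import AssayDesign, TrueMutantProfile


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def subjects():
    return load_table2_fixture()


@pytest.fixture
def responsive_profile():
    """A strongly chaperone-responsive mutant (parameters of the assay's
    positive-control scale: baseline ~5.6 %WT, plateau ~84 %WT, EC50 7.7 µM)."""
    return TrueMutantProfile(
        name="responsive-control", baseline_frac=0.056, top_frac=0.837, ec50_uM=7.7
    )


@pytest.fixture
def noiseless_design():
    return AssayDesign(noise_cv=0.0, between_experiment_cv=0.0, seed=1)


@pytest.fixture
def noisy_design():
    return AssayDesign(noise_cv=0.1, between_experiment_cv=0.1, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
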