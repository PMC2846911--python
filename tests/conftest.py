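import numpy as np
import pytest

from u12scan.fixtures import (fixture_pwm_sets, load_fixture_matrices,
                              load_table1, table1_intron_candidates)
from u12scan.synthetic_data import GeneratorConfig, generate
from u12scan.u12_classify import matrices_from_frequencies


@pytest.fixture(scope="session")
def freqs():
    return load_fixture_matrices()


@pytest.fixture(scope="session")
def pwm_sets(freqs):
    return fixture_pwm_sets(freqs)


@pytest.fixture(scope="session")
def scheme_matrices(freqs):
    return matrices_from_frequencies(freqs)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_candidates():
    return table1_intron_candidates()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact error-free synthetic data set shared across tests."""
    return generate(GeneratorConfig(seed=11, n_genes=15, est_error_rate=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
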