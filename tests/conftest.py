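import numpy as np
import pytest

from traitwalk import fit_trait_scape, make_reference_fixture


@pytest.fixture(scope="session")
def reference_fixture():
    return make_reference_fixture()


@pytest.fixture(scope="session")
def ref_table(reference_fixture):
    return reference_fixture[0]


@pytest.fixture(scope="session")
def ref_corr(reference_fixture):
    return reference_fixture[1]


@pytest.fixture(scope="session")
def ref_scape(ref_table):
    return fit_trait_scape(ref_table, focal_genotype="G1", n_axes=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
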