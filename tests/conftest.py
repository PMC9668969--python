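import numpy as np
import pytest

from lipidflux.thermo import build_affinity_matrix, load_packaged_table


@pytest.fixture(scope="session")
def table():
    return load_packaged_table()


@pytest.fixture(scope="session")
def k_wt(table):
    return build_affinity_matrix(table, "WT_CA")


@pytest.fixture(scope="session")
def k_elic5(table):
    return build_affinity_matrix(table, "ELIC5_CA")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
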