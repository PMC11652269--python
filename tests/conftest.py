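import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from sgsearch.engine import ScoringScheme

hypothesis_settings.register_profile("deterministic", derandomize=True,
                                     deadline=None)
hypothesis_settings.load_profile("deterministic")
from sgsearch.synthetic import generate_database, generate_iid_sequence
from sgsearch.table import SGTableConfig, build_sg_table


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme.from_name("BLOSUM62", 11, 1)


@pytest.fixture(scope="session")
def sg_table_1e6():
    """SG_50 table at N=1e6, default generator/proposal parameters."""
    return build_sg_table(SGTableConfig(m=50, n_draws=10**6, seed=101))


@pytest.fixture(scope="session")
def sg_table_1e7():
    """SG_50 table at N=1e7 — precise enough for tail work down to ~1e-9."""
    return build_sg_table(SGTableConfig(m=50, n_draws=10**7, seed=202))


@pytest.fixture(scope="session")
def toy_db():
    """Ten iid subjects of lengths 30-60, fixed seed."""
    return generate_database(10, (30, 60), seed=11)


@pytest.fixture(scope="session")
def toy_query():
    return generate_iid_sequence(40, seed=12, id="query40")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
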