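import numpy as np
import pytest

from cavedate import DemographicParams, TableSpec, make_site_table


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_params():
    """Reduced-scale demographic configuration for fast simulation tests."""
    return DemographicParams(n_anc=1000, n_sf=1000, n_cf=125, max_years=4000)


@pytest.fixture(scope="session")
def clean_table():
    """A synthetic site table with no filter violations."""
    spec = TableSpec(n_sites={"synonymous": 1200, "non_coding": 400})
    return make_site_table(spec, seed=11)
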