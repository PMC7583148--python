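import numpy as np
import pytest

from crcscreen.absolute import IncidenceTable
from crcscreen.cohort import AGE_MAX, AGE_MIN, SEXES, make_toy_cohort
from crcscreen.defaults import (default_cohort_spec, default_factors,
                                default_family_history_table,
                                default_fh_distribution, default_snp_panel,
                                synthetic_incidence_table,
                                synthetic_projection_frame)
from crcscreen.reporting import PopulationProjection


def constant_incidence(rate: float = 0.001) -> IncidenceTable:
    """Flat incidence table covering 35..83 for closed-form checks."""
    return IncidenceTable({(a, s): rate
                           for a in range(AGE_MIN, AGE_MAX + 10) for s in SEXES})


@pytest.fixture(scope="session")
def factors():
    return default_factors()


@pytest.fixture(scope="session")
def fh_table():
    return default_family_history_table()


@pytest.fixture(scope="session")
def fh_distribution():
    return default_fh_distribution()


@pytest.fixture(scope="session")
def panel():
    return default_snp_panel()


@pytest.fixture(scope="session")
def incidence():
    return synthetic_incidence_table()


@pytest.fixture(scope="session")
def projection():
    return PopulationProjection.from_frame(synthetic_projection_frame())


@pytest.fixture()
def toy_cohort():
    return make_toy_cohort()


@pytest.fixture(scope="session")
def small_spec():
    return default_cohort_spec(seed=7, n=400)
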