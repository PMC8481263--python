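import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pgsrange.synthetic_data import (
    PhantomGeometry,
    SpectrumModel,
    make_campaign_table,
    simulate_campaign,
    simulate_spectrum_record,
)


@pytest.fixture(scope="session")
def campaign_table():
    return make_campaign_table()


@pytest.fixture(scope="session")
def runs_by_dend(campaign_table):
    return {r.d_end: r for r in campaign_table}


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def model():
    return SpectrumModel()


@pytest.fixture(scope="session")
def deep_erb_record(runs_by_dend):
    """Strong-silicon record: beam fully inside the balloon (d_end 3.4)."""
    return simulate_spectrum_record(runs_by_dend[3.4], seed=42)


@pytest.fixture(scope="session")
def prostate_record(runs_by_dend):
    """Null record: beam stops in the prostate (d_end 7.4)."""
    return simulate_spectrum_record(runs_by_dend[7.4], seed=42)


@pytest.fixture(scope="session")
def reference_campaign():
    """Small full campaign archive (10 records, water-only balloon)."""
    return simulate_campaign("reference", seed=5)
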