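import warnings

import pytest

from childev.pipeline import RunConfig, build_synthetic_panel
from childev.simulate import SimConfig, simulate_microdata
from childev.typology import classify


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(
        n_countries=4,
        regions_per_country=3,
        survey_years=(1995, 2005, 2015),
        respondents_per_region_survey=250,
        seed=20260101,
    )


@pytest.fixture(scope="session")
def microdata(sim_config):
    return simulate_microdata(sim_config)


@pytest.fixture(scope="session")
def classified(microdata):
    micro, _ = microdata
    return classify(micro)


@pytest.fixture(scope="session")
def female_panel(sim_config):
    """Complete region-year panel with lagged development/HIV/sex-ratio."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cells, truth, _ = build_synthetic_panel(RunConfig(sim=sim_config), "female")
    return cells, truth
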