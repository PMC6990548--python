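import numpy as np
import pytest

from geoadditive.model import MCMCConfig, fit_model
from geoadditive.survey_synth import SynthDesign, simulate_survey


@pytest.fixture(scope="session")
def small_survey():
    """A modest 24-district survey (~1100 children) shared across tests."""
    design = SynthDesign(
        n_districts=24, clusters_per_district=3, households_per_cluster=8, seed=11
    )
    return simulate_survey(design)


@pytest.fixture(scope="session")
def m3_fit(small_survey):
    """One geoadditive fit on the shared survey, reused by summary tests."""
    children, graph, _ = small_survey
    return fit_model(
        children, "m3", graph=graph, mcmc=MCMCConfig(n_iter=450, burn_in=150, seed=5)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
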