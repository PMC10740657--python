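import numpy as np
import pytest

from owlshift import (SyntheticConfig, default_taxonomy, fit_envelopes,
                      generate_climate, generate_landscape, project_landscape)


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def world(taxonomy):
    """Default synthetic world, shared across tests that only read it."""
    cfg = SyntheticConfig(seed=11)
    landscape = generate_landscape(cfg, taxonomy)
    climate_now = generate_climate(landscape, cfg, warmed=False)
    climate_2090 = generate_climate(landscape, cfg, warmed=True)
    envelopes = fit_envelopes(landscape, climate_now, cfg.interannual_sd(),
                              taxonomy=taxonomy)
    projection = project_landscape(landscape, climate_2090, envelopes, taxonomy)
    return {
        "config": cfg, "landscape": landscape, "climate_now": climate_now,
        "climate_2090": climate_2090, "envelopes": envelopes,
        "projection": projection,
    }


@pytest.fixture
def small_config():
    """A fast 60x60 world for tests that rebuild landscapes repeatedly."""
    return SyntheticConfig(nrows=60, ncols=60, seed=5)
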