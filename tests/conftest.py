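import numpy as np
import pytest

from rfmscale import (
    ScenarioConfig,
    annualize_daily_records,
    colocate_monitors_with_cells,
    generate_scenario,
)
from rfmscale.grid import GridSpec


def tiny_config(seed: int = 7, **overrides) -> ScenarioConfig:
    """A one-coarse-cell scenario that generates in about a second."""
    defaults = dict(
        seed=seed,
        grid_spec=GridSpec(domain_extent=(288.0, 288.0)),
        n_cities=4,
        city_min_separation_km=50.0,
        n_monitors=30,
        n_sources={"agriculture": 10, "egu_point": 5, "nonegu_point": 8},
        n_states=(2, 2),
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_bundle():
    return generate_scenario(tiny_config())


@pytest.fixture(scope="session")
def bundle():
    """Full-size default scenario: the study conditions."""
    return generate_scenario(ScenarioConfig(seed=20))


@pytest.fixture(scope="session")
def monitors(bundle):
    annual = annualize_daily_records(bundle.monitor_daily)
    return colocate_monitors_with_cells(annual, bundle.grid)


@pytest.fixture(scope="session")
def satellite(bundle):
    return bundle.satellite_on_grid()


@pytest.fixture(scope="session")
def tiny_monitors(tiny_bundle):
    annual = annualize_daily_records(tiny_bundle.monitor_daily)
    return colocate_monitors_with_cells(annual, tiny_bundle.grid)


@pytest.fixture(scope="session")
def tiny_satellite(tiny_bundle):
    return tiny_bundle.satellite_on_grid()
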