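import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vitivuln import bioclim, synthetic

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


SMALL = synthetic.SynthConfig(
    grid_shape=(24, 24), n_regions=12, n_varieties=8, n_macro_regions=4,
    noise_sd=0.2, seed=11, n_members=3)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    synthetic.make_fixture(SMALL, out)
    return out


@pytest.fixture(scope="session")
def small_bundle(small_fixture_dir):
    return synthetic.load_fixture(small_fixture_dir)


@pytest.fixture(scope="session")
def small_regional(small_bundle):
    """Present-period regional bioclim records of the small fixture."""
    clim = small_bundle["climate"]
    regions = small_bundle["regions"]
    cells = bioclim.bioclim_dataset(clim.present)
    return bioclim.regional_bioclim(cells, regions.membership)


def flat_cell(tas=15.0, dtr=8.0, pr=50.0):
    """A 12-month cell with constant conditions, as plain arrays."""
    tas_arr = np.full(12, float(tas))
    return {
        "tas": tas_arr,
        "tasmin": tas_arr - dtr / 2.0,
        "tasmax": tas_arr + dtr / 2.0,
        "pr": np.full(12, float(pr)),
    }
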