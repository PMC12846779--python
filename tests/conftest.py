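import numpy as np
import pytest

from hybridcoast import WorldConfig, generate_world
from hybridcoast.foreshore import HazardCurve, Transect


@pytest.fixture(scope="session")
def small_config():
    """Reduced world for fast unit tests (the pipeline default stays 200x200)."""
    return WorldConfig(nx=60, ny=60, n_transects=12, n_regions=4,
                       n_countries=2)


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_transect(chainage, elevation, current=0.0, restorable=0.0,
                  tid=0, y=0.0, region=0):
    """Minimal transect with a flat hazard curve for wave/design tests."""
    hz = HazardCurve(np.array([2.0, 100.0, 1000.0]),
                     np.array([1.0, 1.5, 2.0]),
                     np.array([1.0, 2.0, 2.5]))
    return Transect(id=tid, anchor_x=0.0, anchor_y=y, bearing_deg=270.0,
                    profile_chainage=np.asarray(chainage, float),
                    profile_elevation=np.asarray(elevation, float),
                    mangrove_width_current=current,
                    mangrove_width_restorable=restorable,
                    region_id=region, hazard=hz, restorable_raw=restorable)
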