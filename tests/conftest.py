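import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from vegtexture.spectral_layers import build_layers
from vegtexture.synthetic_scene import (ScenarioConfig, generate_scene,
                                        generate_stem_table)
from vegtexture.texture_features import extract_features

settings.register_profile(
    "ci", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> ScenarioConfig:
    return ScenarioConfig(seed=11)


@pytest.fixture(scope="session")
def scene(default_config):
    return generate_scene(default_config)


@pytest.fixture(scope="session")
def stems(default_config):
    return generate_stem_table(default_config)


@pytest.fixture(scope="session")
def features(scene):
    """Texture feature table of the default synthetic scene (15 plots x 40)."""
    return extract_features(build_layers(scene.bands), scene.plot_registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def single_plot_stems(rows) -> pd.DataFrame:
    """Helper: a stem table for one plot from (species, dbh, d1, d2, h, quad, cls)."""
    return pd.DataFrame(
        [{"plot_id": "P01", "quadrat": q, "species": sp, "dbh_cm": dbh,
          "crown_d1_m": d1, "crown_d2_m": d2, "height_m": h,
          "sampling_class": cls}
         for sp, dbh, d1, d2, h, q, cls in rows]
    )
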