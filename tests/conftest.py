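import numpy as np
import pandas as pd
import pytest

import avistack as av


@pytest.fixture(scope="session")
def small_env():
    """A 60x60 stack with two correlated climate layers and a land-cover layer."""
    return av.make_landscape(
        60,
        60,
        [
            av.LayerSpec("bio1", "continuous", 0.0),
            av.LayerSpec("bio12", "continuous", 0.4),
            av.LayerSpec("LC", "categorical", 0.0, n_classes=4),
        ],
        seed=101,
    )


@pytest.fixture(scope="session")
def linear_species(small_env):
    """Low-prevalence virtual species responding linearly to bio1."""
    return av.make_virtual_species(
        small_env, {"intercept": -3.0, "bio1": 2.0}, species="sp_linear"
    )


@pytest.fixture()
def occurrence_table():
    """Hand-built raw occurrence table exercising each cleaning rule."""
    return pd.DataFrame(
        {
            "species": ["a", "a", "a", "b", "b", "b", "c"],
            "longitude": [10.0, 10.0, 10.5, 11.0, np.nan, 11.2, 200.0],
            "latitude": [50.0, 50.0, 50.5, 51.0, 51.0, 51.2, 50.0],
            "date": [
                "2015-06-01",
                "2015-06-01",  # exact duplicate of the first row
                "2016-07-01",
                "2012-12-31",  # outside the window
                "2018-01-01",  # missing longitude
                "2018-01-01",
                "2018-01-01",  # outside the extent
            ],
            "residency": "resident",
            "diet": "carnivorous",
            "china_class": "none",
            "iucn": "LC",
        }
    )
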