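import numpy as np
import pandas as pd
import pytest

import paramodiv as pv

# published two-decimal mean-crown-age rates for the 13 Páramo lineages
PARAMO_MEAN_RATES = {
    "Aragoa": 5.10,
    "Arcytophyllum": 0.18,
    "Berberis": 0.73,
    "Calceolaria": 1.39,
    "Draba": 1.09,
    "Espeletiinae": 1.01,
    "Festuca": 0.68,
    "Jamesonia+Eriosorus": 0.36,
    "Lupinus": 2.38,
    "Lysipomia": 0.29,
    "Oreobolus": 0.30,
    "Puya": 3.92,
    "Valeriana": 0.22,
}


@pytest.fixture(scope="session")
def paramo_records():
    return pv.load_paramo_lineages()


@pytest.fixture(scope="session")
def hotspot_metas():
    return pv.load_hotspot_metadata()


@pytest.fixture(scope="session")
def paramo_rate_table(paramo_records):
    return pv.rate_table(paramo_records)


@pytest.fixture
def three_tip_tree():
    return pv.chronogram_from_string("((A:1.0,B:1.0):3.0,C:4.0);")


@pytest.fixture
def balanced_tree():
    return pv.chronogram_from_string("((A:2.0,B:2.0):2.0,(C:3.0,D:3.0):1.0);")


@pytest.fixture
def two_hotspot_table():
    """k=1 draws give P(X fastest) = 3/4 exactly: X wins unless (1, 2) drawn."""
    return pd.DataFrame(
        {
            "lineage_id": ["x1", "x2", "y1", "y2"],
            "hotspot": ["X", "X", "Y", "Y"],
            "rate": [3.0, 1.0, 2.0, 0.0],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20130192)
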