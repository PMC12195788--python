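import numpy as np
import pandas as pd
import pytest

from basketcost import data
from basketcost.synthetic_data import SyntheticConfig


@pytest.fixture(scope="session")
def reference_basket():
    return data.load_reference_basket()


@pytest.fixture(scope="session")
def targets():
    return data.load_targets()


@pytest.fixture(scope="session")
def reference_shares():
    return data.reference_shares()


@pytest.fixture(scope="session")
def reference_fti():
    return data.reference_fti()


@pytest.fixture(scope="session")
def nutrient_totals_table():
    return data.load_reference_nutrient_totals()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_cfg():
    """Synthetic config scaled down for fast unit tests."""
    return SyntheticConfig(
        seed=7,
        n_households=300,
        strata=("Q1", "Q2"),
        window_start=(2019, 10),
        window_end=(2021, 12),
        segment_breaks=((2020, 6),),
    )


def make_records(quantities: dict, stratum: str = "Q1", subgroup: str = "veg") -> pd.DataFrame:
    """Single-subgroup consumption records from an {item: quantity} dict."""
    return pd.DataFrame(
        {
            "item": list(quantities),
            "stratum": stratum,
            "subgroup": subgroup,
            "quantity": list(quantities.values()),
        }
    )
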