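import numpy as np
import pandas as pd
import pytest

import diimlm as d


@pytest.fixture(scope="session")
def small_reference():
    return d.generate_reference_table(10, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_reference):
    """300 participants, 20 foods, 10 nutrients, no planted outliers."""
    cfg = d.SimulationConfig(
        n_participants=300, n_foods=20, n_nutrients=10,
        outlier_energy_fraction=0.0, seed=101,
    )
    return d.generate_cohort(cfg, small_reference)


@pytest.fixture(scope="session")
def outlier_cohort():
    """1000 participants with planted energy outliers (default fraction)."""
    cfg = d.SimulationConfig(n_participants=1000, n_foods=30, n_nutrients=12, seed=77)
    return d.generate_cohort(cfg, d.generate_reference_table(12, seed=11))


@pytest.fixture
def toy_composition():
    return pd.DataFrame(
        {"nutrient_a": [2.0, 1.0], "nutrient_b": [0.0, 5.0]},
        index=["rice", "beans"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
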