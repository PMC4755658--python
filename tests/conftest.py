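import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fdrobust as fr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


WORKED_ABUNDANCES = np.array([1, 2, 3, 4, 4, 7, 9, 14, 33, 89], dtype=float)


@pytest.fixture
def worked_abundances():
    """The 10-species plot used throughout as a hand-checkable walkthrough."""
    return WORKED_ABUNDANCES.copy()


@pytest.fixture
def worked_cm(worked_abundances):
    species = [f"s{i:02d}" for i in range(1, 11)]
    return fr.CommunityMatrix(
        pd.DataFrame([worked_abundances], index=["plot1"], columns=species)
    )


@pytest.fixture
def mixed_traits():
    """Five species, two continuous and one categorical trait, one missing cell."""
    df = pd.DataFrame(
        {
            "height": [2.0, 8.0, 5.0, 1.0, 9.0],
            "mass": [0.1, 4.0, np.nan, 0.5, 2.0],
            "form": ["herb", "shrub", "herb", "herb", "tree"],
        },
        index=[f"sp{i}" for i in range(1, 6)],
    )
    return fr.TraitTable(df, {"height": "continuous", "mass": "continuous",
                              "form": "categorical"})


@pytest.fixture
def small_dataset():
    """Seeded synthetic community small enough for end-to-end pipeline tests."""
    config = fr.SynthConfig(
        n_plots=8, n_species=20, sdlog=1.2, occupancy=0.7,
        continuous_traits={"size": 0.8, "mass": 1.2},
        categorical_traits={"form": 3},
        seed=42,
    )
    return fr.synth_dataset(config)
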