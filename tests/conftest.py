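import numpy as np
import pandas as pd
import pytest

from psmnet import GroupDesign, PSMMatrix, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Dropout-free cohort with planted exclusives and fold changes."""
    config = SimulationConfig(
        n_proteins=400,
        detection_prob=1.0,
        n_exclusive_per_group=15,
        n_foldchange_daps=25,
        fold_change=4.0,
        dispersion=50.0,
        seed=7,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Cohort with detection dropout, the structure the IF filters target."""
    config = SimulationConfig(
        n_proteins=300,
        detection_prob=0.85,
        n_exclusive_per_group=10,
        n_foldchange_daps=20,
        fold_change=3.0,
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture()
def toy_matrix():
    """Tiny hand-checkable two-group matrix."""
    values = pd.DataFrame(
        {
            "a1": [10, 0, 5, 1],
            "a2": [12, 0, 4, 0],
            "b1": [0, 8, 5, 1],
            "b2": [0, 9, 6, 0],
            "b3": [0, 7, 5, 2],
        },
        index=["pA", "pB", "pC", "pD"],
    )
    design = GroupDesign({"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"})
    return PSMMatrix(values), design


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
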