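import numpy as np
import pandas as pd
import pytest

from mirscar import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(n_mirnas=200, n_patients=9, n_true_de=10,
                           background_level=50.0, bias_amplitude=0.5,
                           seed=11)
    return simulate_dataset(cfg)


@pytest.fixture()
def tiny_matrix():
    """A hand-sized 4 x 4 expression matrix with two complete pairs."""
    matrix = pd.DataFrame(
        np.array([[8.0, 7.0, 8.2, 7.1],
                  [5.0, 5.5, 4.9, 5.6],
                  [10.0, 10.0, 10.1, 9.9],
                  [3.0, 2.0, 3.1, 2.2]]),
        index=pd.Index([f"mir-{i}" for i in range(1, 5)], name="mirna_id"),
        columns=["p1_scar", "p1_normal", "p2_scar", "p2_normal"],
    )
    sheet = pd.DataFrame({
        "array_id": matrix.columns,
        "patient_id": ["p1", "p1", "p2", "p2"],
        "condition": ["scar", "normal", "scar", "normal"],
    })
    return matrix, sheet
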