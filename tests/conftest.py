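import numpy as np
import pandas as pd
import pytest

from seramir import CountMatrix, SimulationConfig, simulate_counts, simulate_null


@pytest.fixture(scope="session")
def small_null_dataset():
    """Null data, default 8 patients vs 22 controls, 300 miRNAs."""
    return simulate_null(SimulationConfig(n_mirnas=300, dispersion=0.2, seed=101))


@pytest.fixture(scope="session")
def planted_dataset():
    """5% truly differential miRNAs at |log2FC| = 2, moderate dispersion."""
    return simulate_counts(
        SimulationConfig(
            n_mirnas=300, frac_de=0.05, lfc_magnitude=2.0, dispersion=0.1, seed=202
        )
    )


@pytest.fixture
def toy_counts():
    """Tiny handwritten count matrix, 8 miRNAs x 3 samples."""
    rng = np.random.default_rng(7)
    df = pd.DataFrame(
        {
            "s1": [120, 30, 0, 500, 44, 10, 260, 90],
            "s2": [100, 45, 12, 480, 50, 0, 300, 70],
            "s3": [240, 70, 20, 990, 85, 25, 610, 150],
        },
        index=[f"mir-{i}" for i in range(8)],
    )
    return CountMatrix(df)


@pytest.fixture
def two_group_sheet():
    def make(samples, n_patients):
        return pd.DataFrame(
            {
                "sample_id": list(samples),
                "group": ["patient"] * n_patients
                + ["control"] * (len(samples) - n_patients),
                "disease": "toy",
            }
        )

    return make
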