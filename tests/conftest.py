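import numpy as np
import pandas as pd
import pytest

from ktsp.io import ExpressionMatrix
from ktsp.simulate import SyntheticConfig, generate_cohort


@pytest.fixture
def tiny_rpkm() -> ExpressionMatrix:
    df = pd.DataFrame(
        {"S1": [1.0, 1.0, 1.0, 1.0], "S2": [2.0, 0.0, 0.0, 0.0]},
        index=["G1", "G2", "G3", "G4"],
    )
    return ExpressionMatrix(df, "rpkm")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but signal-bearing cohort shared across tests (read-only)."""
    return generate_cohort(
        SyntheticConfig(n_genes=200, n_sensitive=25, n_resistant=40,
                        n_truth_pairs=5, seed=42)
    )


def separable_toy():
    """4 samples, 2 genes: gene A > gene B exactly in the sensitive class."""
    df = pd.DataFrame(
        {
            "s1": [5.0, 1.0], "s2": [6.0, 2.0],
            "r1": [1.0, 5.0], "r2": [2.0, 6.0],
        },
        index=["GA", "GB"],
    )
    labels = ["sensitive", "sensitive", "resistant", "resistant"]
    return df, labels
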