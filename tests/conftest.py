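import numpy as np
import pandas as pd
import pytest

from difcore import CountMatrix
from difcore.simulate import SimulationConfig, generate_counts


@pytest.fixture(scope="session")
def small_cm() -> CountMatrix:
    """Tiny deterministic 2x3 count matrix for contract tests."""
    counts = pd.DataFrame(
        {
            "F1": [10, 100, 30, 0, 7],
            "F2": [12, 110, 28, 0, 8],
            "F3": [9, 95, 35, 1, 6],
            "S1": [40, 20, 31, 0, 7],
            "S2": [38, 25, 29, 0, 9],
            "S3": [45, 18, 33, 0, 6],
        },
        index=[f"g{i}" for i in range(5)],
    )
    conditions = pd.Series(["F"] * 3 + ["S"] * 3, index=counts.columns)
    return CountMatrix(counts, conditions)


@pytest.fixture(scope="session")
def null_sim():
    """2,000-gene null simulation (no DE, NB dispersion 0.1), study design."""
    config = SimulationConfig(n_genes=2000, de_fraction=0.0, dispersion=0.1, seed=11)
    cm, truth = generate_counts(config)
    return config, cm, truth


@pytest.fixture(scope="session")
def planted_sim():
    """Planted-DE simulation: 200 DE at |lfc|=2 among 2,000, alpha=0.1, n=3."""
    config = SimulationConfig(
        n_genes=2000, de_fraction=0.1, lfc_values=(2.0, -2.0), dispersion=0.1, seed=5
    )
    cm, truth = generate_counts(config)
    return config, cm, truth
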