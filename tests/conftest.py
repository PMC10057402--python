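import numpy as np
import pandas as pd
import pytest

from toxpotency import SimConfig, simulate_experiment
from toxpotency.datatypes import ExpressionMatrix

DOSES = (0.0, 6.0, 18.0, 54.0)


@pytest.fixture(scope="session")
def small_experiment():
    """A compact seeded experiment shared by read-only tests."""
    cfg = SimConfig(
        n_genes=120,
        n_responsive=40,
        n_modules=5,
        module_size_range=(8, 15),
        seed=42,
    )
    em, truth = simulate_experiment(cfg)
    return cfg, em, truth


@pytest.fixture()
def toy_matrix():
    """Deterministic 4-gene matrix with two dose groups for hand checks."""
    values = pd.DataFrame(
        {
            "c1": [1.0, 0.0, 1.0, 5.0],
            "c2": [2.0, 0.0, 2.0, 5.0],
            "t1": [4.0, 1.0, 1.0, 5.0],
            "t2": [5.0, 1.0, 2.0, 5.0],
        },
        index=["up", "step", "flat_pair", "constant"],
    )
    samples = pd.DataFrame(
        {
            "exposure": ["E"] * 4,
            "dose": [0.0, 0.0, 54.0, 54.0],
            "replicate": [1, 2, 1, 2],
        },
        index=values.columns,
    )
    return ExpressionMatrix(values, samples)


def make_matrix(values: np.ndarray, doses, exposure="E") -> ExpressionMatrix:
    """Wrap a raw array (genes x samples) with dose metadata."""
    doses = np.asarray(doses, float)
    cols = [f"s{i}" for i in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])], columns=cols)
    meta = pd.DataFrame(
        {"exposure": exposure, "dose": doses, "replicate": np.arange(values.shape[1])},
        index=cols,
    )
    return ExpressionMatrix(vdf, meta)
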