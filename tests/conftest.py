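import numpy as np
import pandas as pd
import pytest

from panelnet.normalize import normalize_dataset
from panelnet.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated paired dataset at default settings, seed 1."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def normalized_default(default_dataset):
    raw, meta, truth = default_dataset
    out = normalize_dataset(raw)
    expr = out.normalized.values[out.normalized.kept_samples]
    return out, expr, meta, truth


def random_symmetric_adjacency(rng: np.random.Generator, n: int) -> pd.DataFrame:
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)
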