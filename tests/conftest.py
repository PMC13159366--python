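import numpy as np
import pandas as pd
import pytest

from heterosim.simulate import SimConfig, generate_design, simulate_study


@pytest.fixture(scope="session")
def small_design():
    return generate_design((10, 10, 10), seed=0)


@pytest.fixture(scope="session")
def tiny_study():
    """A small but complete synthetic study shared across tests."""
    cfg = SimConfig(n_per_group=(12, 12, 12), n_genera=40, n_metabolites=60,
                    n_genes=80, depth=20_000, n_cascades=3, seed=7)
    return simulate_study(cfg)


def gaussian_groups(means, n=(10, 10, 10), sd=1.0, seed=0, n_features=1):
    """Feature matrix + design with given group means (P1, F1, P2)."""
    rng = np.random.default_rng(seed)
    design = generate_design(n, seed=0)
    cols = []
    for g, m in zip(("P1", "F1", "P2"), means):
        k = dict(zip(("P1", "F1", "P2"), n))[g]
        cols.append(rng.normal(m, sd, size=(n_features, k)))
    X = pd.DataFrame(np.concatenate(cols, axis=1),
                     index=[f"f{i}" for i in range(n_features)],
                     columns=design["sample_id"].tolist())
    return X, design
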