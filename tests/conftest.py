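import numpy as np
import pandas as pd
import pytest

from qsig.io import ExpressionMatrix
from qsig.simulate import SimConfig, TissueSpec, generate_experiment


def small_config(seed: int = 3, **overrides) -> SimConfig:
    """Down-scaled two-tissue experiment for fast unit tests."""
    defaults = dict(seed=seed, n_genes=400, signature_size=30, module_size=15,
                    n_decoy_sets=3, n_module_pathways=3)
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_experiment():
    return generate_experiment(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_logmatrix(rng):
    """20 genes x 6 samples log-scale fixture with group structure."""
    vals = rng.normal(5.0, 1.5, size=(20, 6))
    genes = [f"G{i:03d}" for i in range(20)]
    samples = [f"s{j}" for j in range(6)]
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples),
                            scale="log_generic")


@pytest.fixture()
def two_group_design():
    return pd.DataFrame({
        "sample": [f"s{j}" for j in range(6)],
        "tissue": ["t"] * 6,
        "line": ["l1"] * 6,
        "phenotype": ["PKH26_plus"] * 3 + ["PKH26_minus"] * 3,
        "replicate": [1, 2, 3, 1, 2, 3],
    })
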