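import numpy as np
import pandas as pd
import pytest

from plsde.normalization import ExpressionMatrix
from plsde.synthetic import SimulationConfig, generate_bundle


def make_matrix(values: np.ndarray, labels: list[str] | None = None) -> ExpressionMatrix:
    """Wrap a features x samples array in an ExpressionMatrix with toy ids."""
    p, n = values.shape
    fids = [f"f{i + 1}" for i in range(p)]
    sids = [f"s{j + 1}" for j in range(n)]
    lab = pd.Series(labels, index=sids, name="class") if labels is not None else None
    return ExpressionMatrix(pd.DataFrame(values, index=fids, columns=sids), lab)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_class_matrix(rng):
    """12 features x 10 samples, two balanced classes, 2 spiked features."""
    x = rng.normal(8.0, 1.0, size=(12, 10))
    x[0, 5:] += 2.0
    x[1, 5:] -= 2.0
    return make_matrix(x, ["gradeIII"] * 5 + ["gradeIV"] * 5)


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced-size synthetic bundle shared by read-only tests."""
    cfg = SimulationConfig(n_features=80, n_spiked=6, n_class_a=12, n_class_b=18,
                           n_gene_features=100, seed=42)
    return generate_bundle(cfg)
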