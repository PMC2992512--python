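import numpy as np
import pandas as pd
import pytest

from evnet.datatypes import ExpressionMatrix
from evnet.simulate import SimConfig


def make_matrix(values, scale="intensity", meta=None):
    """Build an ExpressionMatrix from a 2-D array with generated ids."""
    values = np.asarray(values, dtype=float)
    rows = [f"g{i}" for i in range(values.shape[0])]
    cols = [f"s{j}" for j in range(values.shape[1])]
    frame = pd.DataFrame(values, index=rows, columns=cols)
    return ExpressionMatrix(frame, meta, scale)


@pytest.fixture
def small_config():
    """A fast, fully featured synthetic study (400 genes, 60 samples)."""
    return SimConfig(
        n_genes=400,
        n_samples=60,
        n_tissues=4,
        n_terms=60,
        term_size_range=(4, 40),
        layer_sizes={"GM": 15, "SF": 20, "GR": 30, "RS": 50, "RS2": 60,
                     "other": 225},
        seed=7,
    )


@pytest.fixture
def tiny_ev():
    """A hand-sized EV table with distinct values."""
    genes = [f"g{i}" for i in range(10)]
    return pd.DataFrame({
        "ev": [0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
        "mean_expr": 100.0,
        "n_samples_used": 20,
        "dataset_tag": "expo_style",
    }, index=genes)
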