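import numpy as np
import pandas as pd
import pytest

from lncprior.io_formats import CountMatrix, ExpressionMatrix
from lncprior.synthetic_data import SimulationConfig


@pytest.fixture
def small_sim_cfg() -> SimulationConfig:
    """A fast-but-complete simulation configuration for unit tests."""
    return SimulationConfig(
        seed=7,
        n_genes=300,
        n_lncRNAs=50,
        module_sizes=(40, 30),
        n_dev_samples=60,
        n_tissues=12,
        n_brain_tissues=3,
        n_cnvs=40,
        n_risk_genes=12,
        n_risk_in_module=8,
        n_lnc_in_module=5,
        n_brain_selective=10,
        n_top_priority=2,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_count_matrix(data, conditions, subjects=None) -> CountMatrix:
    """Build a CountMatrix from a 2-D array and per-column condition labels."""
    data = np.asarray(data)
    cols = [f"s{i+1}" for i in range(data.shape[1])]
    subjects = subjects or cols
    counts = pd.DataFrame(data, index=[f"g{i+1}" for i in range(data.shape[0])], columns=cols)
    samples = pd.DataFrame({"sample": cols, "condition": conditions, "subject": subjects})
    return CountMatrix(counts=counts, samples=samples)


def make_expression_matrix(values, meta=None) -> ExpressionMatrix:
    values = pd.DataFrame(values)
    values.index = [f"g{i+1}" for i in range(len(values))]
    values.columns = [f"s{j+1}" for j in range(values.shape[1])]
    if meta is None:
        meta = pd.DataFrame(index=pd.Index(values.columns, name="sample"))
    return ExpressionMatrix(values=values, meta=meta)
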