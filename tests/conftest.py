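import numpy as np
import pandas as pd
import pytest

from modflow.io_formats import OmicsMatrix
from modflow.synthetic_data import SimulationConfig, simulate_study


SMALL_CONFIG = SimulationConfig(
    n_genes=200,
    module_size=20,
    background_edge_prob=0.03,
    module_edge_prob=0.7,
    n_case=20,
    n_control=20,
    n_datasets_per_omic=2,
    n_risk_sets=3,
    risk_set_size=40,
)


@pytest.fixture(scope="session")
def small_study():
    """A small but fully signalled synthetic study, shared across tests."""
    return simulate_study(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def default_study():
    """The reference study at its default conditions (one instance)."""
    return simulate_study(seed=7)


def make_matrix(values, genes=None, n_case=None, kind="expression"):
    """Build an OmicsMatrix from a plain array, first n_case columns = cases."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    n_case = n_case if n_case is not None else n_samples // 2
    samples = [f"s{i}" for i in range(n_samples)]
    labels = pd.Series(
        ["case"] * n_case + ["control"] * (n_samples - n_case), index=samples
    )
    df = pd.DataFrame(values, index=genes, columns=samples)
    return OmicsMatrix(values=df, labels=labels, kind=kind)
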