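import numpy as np
import pytest

from radeq import FeatureTable, Selection, SimulationSpec, generate_radiomic_dataset, preprocess


def make_selection(indices, d, n_requested=None):
    """Build a Selection from explicit feature positions."""
    indices = np.asarray(sorted(indices), dtype=int)
    indicator = np.zeros(d, dtype=int)
    indicator[indices] = 1
    return Selection(indices, indicator, n_requested or len(indices))


def make_table(values, outcome, names=None, ids=None):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return FeatureTable(
        values,
        outcome,
        names or [f"f{j}" for j in range(d)],
        ids or [f"s{i}" for i in range(n)],
    )


@pytest.fixture(scope="session")
def block_table():
    """Correlated-block table with a sparse planted signal, preprocessed."""
    spec = SimulationSpec(
        n_samples=200,
        n_features=80,
        n_informative=4,
        effect_size=1.5,
        block_sizes=[10] * 8,
        within_block_rho=0.8,
        event_rate=0.4,
        missing_rate=0.0,
        seed=7,
    )
    table = generate_radiomic_dataset(spec)
    prepped, _ = preprocess(table)
    return prepped
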