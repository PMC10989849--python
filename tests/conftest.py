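import numpy as np
import pandas as pd
import pytest

from ecolinks import AbundanceTable, AssociationNetwork


@pytest.fixture
def worked_network():
    """3-taxon network: (T1,T2)=+0.6, (T1,T3)=-0.4."""
    return AssociationNetwork.from_edges(
        ["T1", "T2", "T3"],
        [("T1", "T2", 0.6), ("T1", "T3", -0.4)],
    )


@pytest.fixture
def small_table():
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.integers(0, 50, size=(6, 4)).astype(float),
        index=[f"S{i}" for i in range(6)],
        columns=[f"T{i}" for i in range(4)],
    )
    data.iloc[0, 0] = 1.0  # ensure no zero-sum rows
    return AbundanceTable(data)


@pytest.fixture
def filter_fixture_8samples():
    """8-sample table exercising the >25% occurrence / >=0.001% mean
    relative abundance filter: 'filler' and 'T_keep' survive, 'T_rare_occ'
    (1/8 samples) and 'T_low_abund' (ubiquitous but ~5e-6 mean relabund)
    do not."""
    data = pd.DataFrame(
        {
            "filler": [1e6] * 8,
            "T_keep": [60.0, 80.0, 100.0, 0, 0, 0, 0, 0],
            "T_rare_occ": [50.0, 0, 0, 0, 0, 0, 0, 0],
            "T_low_abund": [5.0] * 8,
        },
        index=[f"S{i}" for i in range(8)],
    )
    return AbundanceTable(data)
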