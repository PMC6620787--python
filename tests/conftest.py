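import numpy as np
import pandas as pd
import pytest

from daquscope.otu_core import OtuTable
from daquscope.simulate import CommunitySpec, simulate_community, simulate_taxonomy


def make_table(counts: dict, groups: dict, lineage=None) -> OtuTable:
    """Build a small OtuTable from {otu: [counts per sample]} and
    {sample: group}."""
    samples = list(groups)
    df = pd.DataFrame(counts, index=samples).T.astype(np.int64)
    meta = pd.DataFrame(
        {"sample_id": samples, "group": [groups[s] for s in samples]}
    ).set_index("sample_id")
    return OtuTable(counts=df, metadata=meta, lineage=lineage)


@pytest.fixture
def tiny_table():
    return make_table(
        {"otu1": [5, 0, 3], "otu2": [10, 2, 0], "otu3": [0, 0, 7]},
        {"s1": "W", "s2": "W", "s3": "Y"},
    )


@pytest.fixture(scope="session")
def community():
    """Moderate two-group community with 3 spiked OTUs (session-scoped)."""
    spec = CommunitySpec(
        groups=[("W", 12), ("Y", 12)],
        n_otus=40,
        markers=[(0, "Y", 3.0), (1, "Y", 3.0), (2, "Y", -3.0)],
        seed=1234,
    )
    return simulate_community(spec)


@pytest.fixture(scope="session")
def tree():
    return simulate_taxonomy(seed=7)
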