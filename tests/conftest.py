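import numpy as np
import pytest

from chronosplice import simulate
from chronosplice.io import LabelledNetwork, TimeCourseMatrix


@pytest.fixture
def times9():
    """Study sampling grid: 6-30 h every 3 h."""
    return np.arange(6.0, 30.1, 3.0)


@pytest.fixture
def small_matrix(times9):
    rng = np.random.default_rng(0)
    values = rng.normal(8.0, 0.5, size=(3, 9))
    return TimeCourseMatrix(["GA", "GB", "GC"], times9, values)


@pytest.fixture
def k2_network():
    """Single SF-NCRG edge."""
    return LabelledNetwork.from_edges(
        [("s1", "n1")], {"s1": {"SF"}, "n1": {"NCRG"}}
    )


@pytest.fixture
def published_degree_network():
    """251 SF / 130 NCRG nodes with exactly 186 distinct cross edges."""
    edges = [(f"SF{i % 251:04d}", f"NCRG{i % 130:04d}") for i in range(186)]
    assert len({frozenset(e) for e in edges}) == 186
    labels = {f"SF{i:04d}": {"SF"} for i in range(251)}
    labels.update({f"NCRG{i:04d}": {"NCRG"} for i in range(130)})
    extra = list(labels)
    return LabelledNetwork.from_edges(edges, labels, extra_nodes=extra)
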