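import numpy as np
import pytest

from cellcoop import RawExpression, SyntheticSpec, simulate
from cellcoop.gene_embedding import GeneGraph


@pytest.fixture
def tiny_raw():
    """4 cells x 3 genes with hand-checkable totals."""
    counts = np.array(
        [
            [1.0, 2.0, 1.0],
            [2.0, 2.0, 0.0],
            [0.0, 3.0, 1.0],
            [1.0, 1.0, 2.0],
        ]
    )
    return RawExpression(
        counts=counts,
        gene_names=["GA", "GB", "GC"],
        cell_ids=["c0", "c1", "c2", "c3"],
        labels=np.array([0, 0, 1, 1]),
    )


@pytest.fixture(scope="session")
def fixture_dataset():
    """The standard synthetic fixture: n=300, k=3, d_g=120."""
    spec = SyntheticSpec(n=300, k=3, d_g=120, separation=2.0,
                         dropout_rate=0.3, seed=7)
    return simulate(spec)


@pytest.fixture
def six_node_graph():
    """Irregular 6-node test graph with triangles and a pendant."""
    edges = {(0, 1), (0, 2), (1, 2), (1, 3), (2, 3), (3, 4), (4, 5)}
    return GeneGraph(nodes=[f"g{i}" for i in range(6)], edges=edges)
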