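import numpy as np
import pytest

from ifcseq.io_formats import CountMatrix, MarkerTable
from ifcseq.synthetic_data import SyntheticTruth, generate_ifc, generate_sct


@pytest.fixture(scope="session")
def truth():
    return SyntheticTruth()


@pytest.fixture(scope="session")
def small_sct(truth):
    """600-cell, 120-gene synthetic SCT experiment (counts, markers, labels)."""
    return generate_sct(truth, n_cells=600, n_genes=120, seed=101)


@pytest.fixture(scope="session")
def small_ifc(truth):
    """300-cell synthetic IFC experiment with images."""
    return generate_ifc(truth, n_cells=300, seed=202, with_images=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_counts(rng):
    vals = rng.integers(0, 6, size=(50, 100)) * (rng.random((50, 100)) < 0.3)
    return CountMatrix(vals.astype(np.int64),
                       [f"g{i}" for i in range(50)],
                       [f"c{j}" for j in range(100)])


@pytest.fixture()
def random_markers(rng):
    return MarkerTable(rng.random((40, 2)) * 8 + 1,
                       [f"c{j}" for j in range(40)],
                       ["m1", "m2"])
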