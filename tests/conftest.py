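import numpy as np
import pytest

from bprsnet import (
    ItemCatalog,
    OrdinalResponseMatrix,
    bprs_catalog,
    make_truth_network,
    reference_item_counts,
    sample_ordinal,
)


@pytest.fixture(scope="session")
def catalog() -> ItemCatalog:
    return bprs_catalog()


@pytest.fixture(scope="session")
def reference_counts():
    return reference_item_counts()


@pytest.fixture(scope="session")
def small_dataset():
    """5 correlated ordinal items, n=400: cheap but non-trivial pipeline input."""
    spec = make_truth_network(
        blocks=(3, 2), within_density=1.0, bridge_count=1, seed=11
    )
    return sample_ordinal(spec, n=400, seed=12)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-scale synthetic study: 18 items, n=1438, planted 10/3/5 blocks."""
    spec = make_truth_network(seed=1)
    return sample_ordinal(spec, n=1438, seed=2)


@pytest.fixture
def tiny_matrix() -> OrdinalResponseMatrix:
    rng = np.random.default_rng(5)
    return OrdinalResponseMatrix(
        values=rng.integers(1, 8, size=(30, 3)),
        item_codes=("A", "B", "C"),
        K=7,
    )
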