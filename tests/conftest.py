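import numpy as np
import pytest

from ppiblocks import ProteinCatalog, generate_synthetic_store


@pytest.fixture
def make_fixture(tmp_path):
    """Factory building a synthetic catalog + HDF5 embedding store."""

    def _make(n=8, dim=8, seed=7, length_range=(10, 25), prefix="fix"):
        ids = [f"p{i:03d}" for i in range(n)]
        store_path = tmp_path / f"{prefix}.h5"
        lengths = generate_synthetic_store(
            ids, length_range, dim, seed, store_path, overwrite=True
        )
        catalog = ProteinCatalog(tuple(ids), tuple(lengths[i] for i in ids))
        return catalog, store_path

    return _make


@pytest.fixture
def small_catalog():
    rng = np.random.default_rng(0)
    n = 10
    return ProteinCatalog(
        tuple(f"q{i}" for i in range(n)),
        tuple(int(x) for x in rng.integers(5, 40, size=n)),
    )
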