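import numpy as np
import pytest

import gczone as g


@pytest.fixture(scope="session")
def packaged_signatures():
    return g.load_packaged_signatures()


@pytest.fixture(scope="session")
def small_gc():
    """A clean, well-separated synthetic GC (no label noise, strong effect)."""
    cfg = g.SyntheticConfig(
        n_cells=800,
        signature_effect=2.0,
        label_noise=0.0,
        seed=7,
    )
    cells, truth = g.generate_gc(cfg)
    return cfg, cells, truth


@pytest.fixture(scope="session")
def default_gc():
    """A synthetic GC at the default study conditions (effect 1.5, 10% noise)."""
    cfg = g.SyntheticConfig(seed=3)
    cells, truth = g.generate_gc(cfg)
    return cfg, cells, truth


@pytest.fixture()
def toy_cell_table():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 6, size=(12, 7))
    return g.CellTable(
        cell_ids=[f"c{i}" for i in range(12)],
        x=rng.uniform(0, 100, 12),
        y=rng.uniform(0, 100, 12),
        counts=counts,
        gene_ids=[f"g{i}" for i in range(7)],
    )
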