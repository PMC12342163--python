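import numpy as np
import pytest

from gprint import io_prep, synthetic


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast simulation used by most integration-flavored tests."""
    return synthetic.SimSpec(
        n_genes=300,
        n_chromosomes=3,
        n_cell_types=3,
        cells_per_type=30,
        signature_block_length=12,
        signature_fold_change=6.0,
        dropout_rate=0.2,
        library_size_spread=0.2,
        batch_effect_sd=0.2,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_sim(tiny_spec):
    ref, truth = synthetic.generate_reference(tiny_spec)
    query, query_labels = synthetic.generate_query(tiny_spec, truth)
    return {"spec": tiny_spec, "ref": ref, "truth": truth,
            "query": query, "query_labels": query_labels}


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(11)
    values = rng.integers(0, 6, size=(8, 12)).astype(float)
    return io_prep.CountMatrix(
        values,
        [f"c{i}" for i in range(8)],
        [f"g{j}" for j in range(12)],
    )


@pytest.fixture
def simple_annotation():
    return io_prep.GeneCoordinateTable(
        ["A", "B", "C", "D"],
        ["chr1", "chr1", "chr2", "chrX"],
        np.array([300, 100, 50, 70]),
    )
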