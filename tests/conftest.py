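import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from flowsc import CountDataset, SimConfig


def make_counts(dense, groups=None, samples=None, cell_types=None, genes=None):
    """Build a CountDataset from a dense genes x cells array (test helper)."""
    dense = np.asarray(dense)
    n_genes, n_cells = dense.shape
    gene_ids = np.array(genes if genes is not None else [f"g{i}" for i in range(n_genes)], dtype=object)
    cell_ids = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
    meta = pd.DataFrame(
        {
            "group": groups if groups is not None else ["d-flow"] * n_cells,
            "sample_id": samples if samples is not None else ["m1"] * n_cells,
        },
        index=pd.Index(cell_ids, name="barcode"),
    )
    if cell_types is not None:
        meta["cell_type"] = cell_types
    return CountDataset(
        counts=sp.csr_matrix(dense.astype(np.int64)),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_meta=meta,
    )


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-size study configuration used by tests that need a full dataset."""
    return SimConfig(
        n_cell_types=7,
        cells_per_type_per_group=40,
        n_genes=600,
        n_marker_genes_per_type=10,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    from flowsc import generate_sc_dataset

    return generate_sc_dataset(small_cfg)
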