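import warnings

import numpy as np
import pandas as pd
import pytest

from gliostate import synthetic as syn

# keep the suite's stderr readable: the pipeline intentionally warns a lot
warnings.filterwarnings("ignore", category=UserWarning, module="gliostate")
warnings.filterwarnings("ignore", category=UserWarning, module="scanpy")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_model():
    """Compact genome: 15 autosomes x 210 genes + 5 mito (signature blocks fit)."""
    return syn.build_genome_model(
        n_chromosomes=15, genes_per_chromosome=210, n_mito=5
    )


@pytest.fixture(scope="session")
def small_dataset(small_model):
    """Two-sample, 300-cell bundle with truth; shared across unit tests."""
    cfg = syn.SimConfig(n_samples=2, cells_per_sample=300, seed=11)
    adata, truth = syn.simulate_dataset(small_model, cfg)
    return adata, truth.set_index("barcode"), cfg


@pytest.fixture()
def tiny_adata():
    """Hand-buildable AnnData factory for arithmetic oracles."""
    import anndata as ad
    import scipy.sparse as sp

    def make(counts, chromosomes=None, positions=None, mito=None, samples=None):
        counts = np.asarray(counts)
        n_cells, n_genes = counts.shape
        var = pd.DataFrame(
            {
                "chromosome": chromosomes
                if chromosomes is not None
                else ["chr1"] * n_genes,
                "position": positions
                if positions is not None
                else np.arange(1, n_genes + 1) * 100,
                "mito": mito if mito is not None else [False] * n_genes,
            },
            index=[f"g{i}" for i in range(n_genes)],
        )
        obs = pd.DataFrame(
            {"sample": samples if samples is not None else ["S1"] * n_cells},
            index=[f"c{i}" for i in range(n_cells)],
        )
        return ad.AnnData(X=sp.csr_matrix(counts.astype(np.int32)), obs=obs, var=var)

    return make
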