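import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import psnpipe as pp
from psnpipe.qc import NormMatrix


def make_norm_matrix(values, chromosomes=None, gene_ids=None, barcodes=None,
                     **meta) -> NormMatrix:
    """Build a NormMatrix from a dense array (genes x cells) for unit tests."""
    values = np.asarray(values, dtype=float)
    G, N = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(G)]
    if chromosomes is None:
        chromosomes = ["1"] * G
    genes = pd.DataFrame({
        "gene_id": gene_ids, "symbol": gene_ids,
        "chromosome": chromosomes,
        "start": 1000 * np.arange(G),
    })
    if barcodes is None:
        barcodes = [f"c{i:04d}" for i in range(N)]
    return NormMatrix(values=sp.csr_matrix(values), genes=genes,
                      barcodes=barcodes, **meta)


@pytest.fixture(scope="session")
def small_cohort():
    """Two patients with paired GG/solid plus one nLung sample; shared by tests."""
    config = pp.default_config(seed=42, n_patients=2, n_nlung_patients=1,
                               n_cells_per_sample=250)
    cohort, truth = pp.simulate_cohort(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def qc_fixture():
    """1000-cell single-sample cohort with every QC violation class planted."""
    from psnpipe.simdata import QcContaminantFractions
    config = pp.default_config(
        seed=7, n_patients=1, n_nlung_patients=0, n_cells_per_sample=1000,
        groups_per_patient=("GG",), n_genes=6500,
        qc_contaminant_fractions=QcContaminantFractions(
            low_genes=0.1, high_genes=0.05, high_mito=0.05, high_umi=0.03),
    )
    cohort, truth = pp.simulate_cohort(config)
    return config, cohort[0], truth
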