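"""Cell/gene quality filters, log-normalization, variable genes and doublet flags.

QC retains cells with 200 <= detected genes <= 6000, mitochondrial UMI
fraction <= 15% and total UMIs <= 60000; genes must be detected in at least
5 cells.  Normalization is ln(UMI / cell_total * 10000 + 1).  Boundary cells
(exactly on a threshold) are retained because the removal rules are phrased
as strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"


def mito_gene_mask(genes: pd.DataFrame) -> np.ndarray:
    """Mitochondrial genes identified by case-insensitive symbol prefix ``MT-``."""
    return genes["symbol"].str.upper().str.startswith(MITO_PREFIX).to_numpy()


@dataclass
class QCSummary:
    """Per-rule removal counts recorded by the filters."""

    cells_in: int = 0
    cells_out: int = 0
    removed_low_genes: int = 0
    removed_high_genes: int = 0
    removed_high_mito: int = 0
    removed_high_umi: int = 0
    genes_in: int = 0
    genes_out: int = 0
    removed_low_cell_genes: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("cells_low_genes", self.removed_low_genes, 0),
            ("cells_high_genes", self.removed_high_genes, 0),
            ("cells_high_mito", self.removed_high_mito, 0),
            ("cells_high_umi", self.removed_high_umi, 0),
            ("genes_min_cells", 0, self.removed_low_cell_genes),
        ]
        return pd.DataFrame(rows, columns=["rule", "cells_removed", "genes_removed"])


def cell_qc_metrics(m: CountMatrix) -> pd.DataFrame:
    """Detected genes, total UMIs and mitochondrial fraction per cell."""
    counts = sp.csc_matrix(m.counts)
    detected = counts.getnnz(axis=0)
    total = np.asarray(counts.sum(axis=0)).ravel()
    mito = mito_gene_mask(m.genes)
    mito_umis = np.asarray(counts[mito, :].sum(axis=0)).ravel() if mito.any() else np.zeros_like(total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_umis / np.maximum(total, 1), 0.0)
    return pd.DataFrame({
        "barcode": m.barcodes,
        "n_genes": detected,
        "n_umis": total,
        "mito_frac": mito_frac,
    })


def filter_cells(
    m: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito_frac: float = 0.15,
    max_umis: int = 60000,
) -> tuple[CountMatrix, QCSummary]:
    """Remove low-quality cells; the returned summary records per-rule removals.

    A cell can violate several rules; the summary attributes it to every rule
    it trips, so rule counts may exceed the number of removed cells.
    """
    metrics = cell_qc_metrics(m)
    low = metrics["n_genes"].to_numpy() < min_genes
    high = metrics["n_genes"].to_numpy() > max_genes
    mito = metrics["mito_frac"].to_numpy() > max_mito_frac
    umi = metrics["n_umis"].to_numpy() > max_umis
    keep = ~(low | high | mito | umi)
    summary = QCSummary(
        cells_in=m.n_cells,
        cells_out=int(keep.sum()),
        removed_low_genes=int(low.sum()),
        removed_high_genes=int(high.sum()),
        removed_high_mito=int(mito.sum()),
        removed_high_umi=int(umi.sum()),
        genes_in=m.n_genes,
        genes_out=m.n_genes,
    )
    if not keep.any():
        logger.warning("sample %s: all %d cells removed by QC", m.sample_id, m.n_cells)
    return m.subset_cells(keep), summary


def filter_genes(m: CountMatrix, min_cells: int = 5) -> tuple[CountMatrix, QCSummary]:
    """Keep genes detected (nonzero) in at least ``min_cells`` cells."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    detected_in = sp.csr_matrix(m.counts).getnnz(axis=1)
    keep = detected_in >= min_cells
    summary = QCSummary(
        cells_in=m.n_cells, cells_out=m.n_cells,
        genes_in=m.n_genes, genes_out=int(keep.sum()),
        removed_low_cell_genes=int((~keep).sum()),
    )
    return m.subset_genes(keep), summary


@dataclass
class NormMatrix:
    """Log-normalized gene x cell expression: ln(count / total * scale_factor + 1).

    Sparsity is preserved (zero counts stay exactly zero).  For every cell with
    positive total, sum_genes(exp(value) - 1) equals ``scale_factor``.
    """

    values: sp.csr_matrix
    genes: pd.DataFrame
    barcodes: list[str]
    sample_id: str = "sample"
    patient_id: str = "patient"
    clinical_group: str = "GG"
    cell_labels: Optional[pd.Series] = None
    scale_factor: float = 10000.0

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset_cells(self, mask: np.ndarray) -> "NormMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        labels = None
        if self.cell_labels is not None:
            labels = self.cell_labels.iloc[idx].reset_index(drop=True)
        return NormMatrix(
            values=self.values[:, idx], genes=self.genes,
            barcodes=[self.barcodes[i] for i in idx],
            sample_id=self.sample_id, patient_id=self.patient_id,
            clinical_group=self.clinical_group, cell_labels=labels,
            scale_factor=self.scale_factor,
        )


def lognormalize(m: CountMatrix, scale_factor: float = 10000.0) -> NormMatrix:
    """Library-size normalize and log-transform: ln(count/total * scale_factor + 1)."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    counts = sp.csc_matrix(m.counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    zero_cells = totals == 0
    if zero_cells.any():
        logger.warning("sample %s: %d cells with zero total counts",
                       m.sample_id, int(zero_cells.sum()))
    scale = np.where(totals > 0, scale_factor / np.maximum(totals, 1.0), 0.0)
    norm = counts.multiply(scale[np.newaxis, :]).tocsr()
    norm.data = np.log1p(norm.data)
    return NormMatrix(
        values=norm, genes=m.genes.reset_index(drop=True), barcodes=list(m.barcodes),
        sample_id=m.sample_id, patient_id=m.patient_id,
        clinical_group=m.clinical_group, cell_labels=m.cell_labels,
        scale_factor=scale_factor,
    )


def standardized_variance(values: sp.spmatrix) -> np.ndarray:
    """Variance-stabilized dispersion per gene (vst-style).

    Per gene: mean/variance of the raw values across cells; a degree-2
    ridge-regularized polynomial of log10(variance) on log10(mean) supplies a
    trend-predicted sd; each entry is z-scored with that sd, clipped at
    sqrt(n_cells), and the gene statistic is the variance of the clipped z.
    Genes with zero variance (or zero mean) score 0.
    """
    X = sp.csr_matrix(values, dtype=np.float64)
    n_genes, n_cells = X.shape
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n_cells / max(n_cells - 1, 1)
    var = np.maximum(var, 0.0)

    ok = (mean > 0) & (var > 0)
    pred_sd = np.zeros(n_genes)
    if np.unique(mean[ok]).size < 3:
        # too few distinct means for a trend: fall back to raw variance ranking
        logger.warning("variable-gene trend skipped: fewer than 3 distinct gene means")
        return var
    lm = np.log10(mean[ok])
    lv = np.log10(var[ok])
    A = np.column_stack([np.ones_like(lm), lm, lm**2])
    ridge = 1e-8 * np.eye(3)
    ridge[0, 0] = 0.0
    coef = np.linalg.solve(A.T @ A + ridge, A.T @ lv)
    pred_sd[ok] = np.sqrt(10 ** (A @ coef))

    clip = np.sqrt(n_cells)
    out = np.zeros(n_genes)
    Xc = sp.csr_matrix(X)
    for g in np.flatnonzero(ok):
        sd = pred_sd[g]
        row = Xc.data[Xc.indptr[g]:Xc.indptr[g + 1]]
        z_nz = np.clip((row - mean[g]) / sd, -clip, clip)
        z0 = np.clip(-mean[g] / sd, -clip, clip)
        n_zero = n_cells - row.size
        s1 = z_nz.sum() + z0 * n_zero
        s2 = (z_nz**2).sum() + z0**2 * n_zero
        mu = s1 / n_cells
        out[g] = (s2 / n_cells - mu**2) * n_cells / max(n_cells - 1, 1)
    return out


def select_variable_genes(matrix, n: int = 2000) -> list[str]:
    """Top ``n`` genes ranked by standardized variance (descending, gene-id tiebreak).

    Accepts a :class:`CountMatrix` (the intended input, matching the counts-based
    convention of the method) or a :class:`NormMatrix`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    values = matrix.counts if isinstance(matrix, CountMatrix) else matrix.values
    sv = standardized_variance(values)
    gene_ids = matrix.genes["gene_id"].to_numpy()
    order = sorted(range(len(gene_ids)), key=lambda i: (-sv[i], gene_ids[i]))
    chosen = [gene_ids[i] for i in order if sv[i] > 0][:n]
    return chosen


def flag_doublets(
    nm: NormMatrix,
    marker_table: Mapping[str, Sequence[str]],
    labels: Optional[pd.Series] = None,
    min_marker_frac: float = 0.5,
) -> np.ndarray:
    """Flag cells co-expressing canonical markers of two or more cell types.

    A marker set counts as expressed in a cell when strictly more than
    ``min_marker_frac`` of its (known) genes have nonzero normalized value.
    Unknown marker genes are ignored with a warning.  ``labels`` is accepted
    for interface symmetry and logging only; the rule is label-free.
    """
    if not marker_table:
        return np.zeros(nm.n_cells, dtype=bool)
    gene_pos = {g: i for i, g in enumerate(nm.genes["symbol"])}
    gene_pos.update({g: i for i, g in enumerate(nm.genes["gene_id"])})
    expressed_sets = np.zeros(nm.n_cells, dtype=int)
    X = sp.csr_matrix(nm.values)
    for ctype, markers in marker_table.items():
        idx = [gene_pos[g] for g in markers if g in gene_pos]
        unknown = [g for g in markers if g not in gene_pos]
        if unknown:
            logger.warning("markers for %s not in matrix: %s", ctype, unknown)
        if not idx:
            continue
        nonzero = (X[idx, :] > 0).sum(axis=0)
        frac = np.asarray(nonzero).ravel() / len(idx)
        expressed_sets += (frac > min_marker_frac).astype(int)
    return expressed_sets >= 2
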