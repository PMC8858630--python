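"""Copy-number signal inference from expression and malignant-cell calling.

The estimator is a minimal moving-average CNV proxy: per-gene residuals
against a reference-cell baseline are clipped, smoothed along genome order
within each chromosome, recentered per cell by its median, and re-standardized
against the reference cells.  Malignant cells are then those whose genome-wide
signal correlates with a reference vector — the gene-wise mean signal of the
cells in the top 5% by mean-square CNV score — with Pearson r above 0.3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, chromosome_sort_key
from .qc import NormMatrix

logger = logging.getLogger(__name__)


@dataclass
class CnvProfile:
    """Re-standardized CNV signal per cell over genome-ordered genes."""

    signal: np.ndarray              # cells x genes
    cell_ids: list[str]
    gene_ids: list[str]             # genome order
    chromosomes: np.ndarray         # per gene, aligned with gene_ids
    reference_cell_ids: list[str]
    window: int
    clip: float

    @property
    def n_cells(self) -> int:
        return self.signal.shape[0]

    @property
    def n_genes(self) -> int:
        return self.signal.shape[1]


@dataclass
class MalignantCall:
    """Per-cell Pearson correlation with the CNV reference vector and the call."""

    cell_ids: list[str]
    r: np.ndarray
    malignant: np.ndarray
    undefined: np.ndarray           # zero-variance rows where r is not defined
    r_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell": self.cell_ids,
            "r": self.r,
            "malignant": self.malignant,
            "undefined_r": self.undefined,
        })


def moving_average_blocks(values: np.ndarray, blocks: Sequence[np.ndarray],
                          window: int) -> np.ndarray:
    """Centered moving average of width ``window`` within each column block.

    At block edges (and for blocks shorter than the window) the window shrinks
    to the genes actually available.
    """
    out = np.empty_like(values, dtype=float)
    h = window // 2
    for idx in blocks:
        block = values[:, idx]
        n = block.shape[1]
        cs = np.cumsum(block, axis=1)
        pos = np.arange(n)
        hi = np.minimum(pos + h, n - 1)
        lo = np.maximum(pos - h, 0)
        upper = cs[:, hi]
        lower = np.where(lo > 0, cs[:, np.maximum(lo - 1, 0)], 0.0)
        out[:, idx] = (upper - lower) / (hi - lo + 1)
    return out


def infer_cnv_profile(
    nm: NormMatrix,
    reference_cells: np.ndarray,
    window: int = 101,
    clip: float = 3.0,
) -> CnvProfile:
    """Infer the smoothed, re-standardized CNV signal for every cell in ``nm``.

    Parameters
    ----------
    nm
        Log-normalized expression with gene coordinates in ``nm.genes``.
        Genes without coordinates (missing chromosome/start) are dropped.
    reference_cells
        Boolean mask over the cells of ``nm`` marking the CNV baseline cells
        (reference cells may also appear as query cells).
    window
        Odd moving-average width in genes, applied within each chromosome.
    clip
        Residuals are clipped to ``[-clip, +clip]`` before smoothing.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    reference_cells = np.asarray(reference_cells, dtype=bool)
    if not reference_cells.any():
        raise ValueError("reference_cells must be non-empty")

    genes = nm.genes
    has_coord = genes["chromosome"].notna() & genes["start"].notna()
    if (~has_coord).any():
        logger.warning("dropping %d genes without coordinates", int((~has_coord).sum()))
    gsub = genes[has_coord]
    order = sorted(
        gsub.index,
        key=lambda i: (chromosome_sort_key(gsub.at[i, "chromosome"]),
                       int(gsub.at[i, "start"]), gsub.at[i, "gene_id"]),
    )
    order = np.asarray(order)

    X = np.asarray(nm.values[order, :].todense()).T        # cells x genes
    chroms = genes["chromosome"].to_numpy()[order]

    ref_mean = X[reference_cells].mean(axis=0)
    resid = np.clip(X - ref_mean, -clip, clip)

    blocks = [np.flatnonzero(chroms == c) for c in pd.unique(chroms)]
    smooth = moving_average_blocks(resid, blocks, window)

    smooth -= np.median(smooth, axis=1, keepdims=True)      # per-cell recentering
    smooth -= smooth[reference_cells].mean(axis=0)          # re-standardize vs reference

    cell_ids = [f"{nm.sample_id}:{b}" if ":" not in b else b for b in nm.barcodes]
    return CnvProfile(
        signal=smooth,
        cell_ids=cell_ids,
        gene_ids=[genes.at[i, "gene_id"] for i in order],
        chromosomes=chroms,
        reference_cell_ids=[c for c, r in zip(cell_ids, reference_cells) if r],
        window=window,
        clip=clip,
    )


def cnv_cell_score(profile: CnvProfile) -> np.ndarray:
    """Per-cell CNV score: the mean square of the re-standardized signals."""
    return np.mean(profile.signal**2, axis=1)


def build_reference_vector(profile: CnvProfile, top_frac: float = 0.05) -> np.ndarray:
    """Gene-wise mean signal of the ceil(top_frac * n_cells) highest-scoring cells.

    Scores are the per-cell mean-square CNV scores; ties at the cutoff are
    broken by cell order for determinism.  Averages SIGNED signals so that the
    amplification/deletion direction is preserved for the correlation step.
    """
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must lie in (0, 1)")
    n = profile.n_cells
    if n == 0:
        raise ValueError("profile has no cells")
    k = max(1, int(np.ceil(top_frac * n)))
    scores = cnv_cell_score(profile)
    top = np.argsort(-scores, kind="stable")[:k]
    return profile.signal[top].mean(axis=0)


def classify_malignant(
    profile: CnvProfile,
    reference_vector: np.ndarray,
    r_threshold: float = 0.3,
) -> MalignantCall:
    """Call a cell malignant when Pearson r(signal, reference) is strictly above 0.3.

    Cells with zero-variance signal (undefined correlation) are non-malignant
    and flagged.
    """
    ref = np.asarray(reference_vector, dtype=float)
    refc = ref - ref.mean()
    ref_norm = np.linalg.norm(refc)
    if ref_norm == 0:
        raise ValueError("reference_vector has zero variance")
    S = profile.signal - profile.signal.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(S, axis=1)
    undefined = norms == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (S @ refc) / (norms * ref_norm)
    r[undefined] = np.nan
    malignant = np.where(undefined, False, r > r_threshold)
    return MalignantCall(
        cell_ids=list(profile.cell_ids),
        r=r,
        malignant=malignant.astype(bool),
        undefined=undefined,
        r_threshold=r_threshold,
    )


def call_malignant_cells(
    nm: NormMatrix,
    reference_cells: np.ndarray,
    window: int = 101,
    clip: float = 3.0,
    top_frac: float = 0.05,
    r_threshold: float = 0.3,
) -> tuple[CnvProfile, np.ndarray, MalignantCall]:
    """End-to-end malignant calling: profile -> reference vector -> correlation call."""
    profile = infer_cnv_profile(nm, reference_cells, window=window, clip=clip)
    ref_vec = build_reference_vector(profile, top_frac=top_frac)
    call = classify_malignant(profile, ref_vec, r_threshold=r_threshold)
    return profile, ref_vec, call
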