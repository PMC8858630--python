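"""Intratumoural expression programs by per-sample NMF and cross-sample meta-programs.

Per sample, the malignant-cell expression matrix is z-scored per gene with
negative values set to zero and factorized by NMF at ranks k = 6..9.  Each
factor defines a program: its top 50 genes by factor loading.  A program is
*robust* when it shares at least 35 of its 50 genes with a program obtained at
a different rank.  Robust programs are pooled across samples (GG and solid
pools separately), hierarchically clustered with distance = 50 - overlap, and
clusters spanning at least two samples become meta-programs, each with a
core-gene set of the genes recurring in at least 25% of the member programs
across at least two samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp
from sklearn.decomposition import NMF

from .qc import NormMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionProgram:
    sample_id: str
    k: int
    factor_index: int
    genes: tuple[str, ...]          # ordered by loading, descending
    scores: tuple[float, ...]

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    @property
    def name(self) -> str:
        return f"{self.sample_id}|k{self.k}|f{self.factor_index}"


@dataclass
class MetaProgram:
    members: list[ExpressionProgram]
    core_genes: set[str] = field(default_factory=set)
    label: str = ""

    @property
    def samples(self) -> set[str]:
        return {p.sample_id for p in self.members}

    @property
    def gene_union(self) -> set[str]:
        out: set[str] = set()
        for p in self.members:
            out |= p.gene_set
        return out


def prepare_matrix(
    nm: NormMatrix,
    cell_mask: Optional[np.ndarray] = None,
    min_cells: int = 20,
) -> tuple[Optional[np.ndarray], list[str]]:
    """Z-score genes across the selected cells and clip negatives to zero.

    Returns ``(matrix, gene_ids)`` with matrix of shape genes x cells, or
    ``(None, [])`` when fewer than ``min_cells`` cells are available (the
    sample is skipped with a log entry).  Zero-variance genes are dropped.
    """
    if cell_mask is None:
        cell_mask = np.ones(nm.n_cells, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    n = int(cell_mask.sum())
    if n < min_cells:
        logger.info("sample %s skipped for NMF: %d cells < floor %d",
                    nm.sample_id, n, min_cells)
        return None, []
    X = np.asarray(nm.values[:, np.flatnonzero(cell_mask)].todense(), dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    keep = sd.ravel() > 0
    Z = (X[keep] - mean[keep]) / sd[keep]
    np.maximum(Z, 0.0, out=Z)
    gene_ids = [g for g, k in zip(nm.genes["gene_id"], keep) if k]
    return Z, gene_ids


def run_nmf(matrix: np.ndarray, k: int, seed: int = 0,
            tol: float = 1e-4, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Factorize a non-negative matrix into W (genes x k) and H (k x cells).

    Uses coordinate descent with NNDSVD (zero-fill) initialization, which is
    deterministic; the seed only matters for solvers that randomize.
    """
    if k < 1 or k >= min(matrix.shape):
        raise ValueError(f"k={k} out of range for matrix of shape {matrix.shape}")
    model = NMF(n_components=k, init="nndsvd", solver="cd", tol=tol,
                max_iter=max_iter, random_state=seed)
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum number of iterations.*")
        W = model.fit_transform(matrix)
    if model.n_iter_ >= max_iter:
        logger.info("NMF k=%d stopped at max_iter=%d (best iterate returned)", k, max_iter)
    return W, model.components_


def extract_programs(
    W: np.ndarray,
    gene_ids: Sequence[str],
    sample_id: str,
    k: int,
    top_n: int = 50,
) -> list[ExpressionProgram]:
    """Top ``top_n`` genes per factor, by loading descending, gene-id tiebreak."""
    if top_n > len(gene_ids):
        raise ValueError("top_n exceeds gene count")
    programs = []
    gene_ids = list(gene_ids)
    for j in range(W.shape[1]):
        loadings = W[:, j]
        order = sorted(range(len(gene_ids)), key=lambda i: (-loadings[i], gene_ids[i]))
        top = order[:top_n]
        programs.append(ExpressionProgram(
            sample_id=sample_id, k=k, factor_index=j,
            genes=tuple(gene_ids[i] for i in top),
            scores=tuple(float(loadings[i]) for i in top),
        ))
    return programs


def program_overlap(p: ExpressionProgram, q: ExpressionProgram) -> int:
    return len(p.gene_set & q.gene_set)


def robust_programs(
    programs: Sequence[ExpressionProgram],
    robust_overlap: int = 35,
) -> list[ExpressionProgram]:
    """Programs sharing >= ``robust_overlap`` genes with a program at a different k."""
    out = []
    for p in programs:
        for q in programs:
            if q.k != p.k and program_overlap(p, q) >= robust_overlap:
                out.append(p)
                break
    return out


def cluster_programs(
    programs: Sequence[ExpressionProgram],
    top_n: int = 50,
    cut: Optional[float] = None,
    robust_overlap: int = 35,
    core_frac: float = 0.25,
    min_samples: int = 2,
) -> tuple[list[MetaProgram], Optional[np.ndarray]]:
    """Average-linkage clustering of programs with distance = top_n - overlap.

    The dendrogram is cut at ``cut`` (default ``top_n - robust_overlap``);
    clusters whose members span at least ``min_samples`` samples become
    meta-programs.  Programs are sorted by (sample, k, factor) first so the
    output is invariant to input order.  Returns the meta-programs and the
    scipy linkage matrix (None when fewer than 2 programs were supplied).
    """
    programs = sorted(programs, key=lambda p: (p.sample_id, p.k, p.factor_index))
    if len(programs) < 2:
        return [], None
    if cut is None:
        cut = float(top_n - robust_overlap)
    m = len(programs)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = top_n - program_overlap(programs[i], programs[j])
            dist[i, j] = dist[j, i] = d
    condensed = dist[np.triu_indices(m, k=1)]
    Z = sch.linkage(condensed, method="average")
    assignments = sch.fcluster(Z, t=cut, criterion="distance")
    metas = []
    for cl in np.unique(assignments):
        members = [programs[i] for i in np.flatnonzero(assignments == cl)]
        mp = MetaProgram(members=members)
        if len(mp.samples) >= min_samples:
            mp.core_genes = core_genes(mp, core_frac=core_frac)
            metas.append(mp)
    metas.sort(key=lambda mp: (-len(mp.members), mp.members[0].name))
    return metas, Z


def core_genes(mp: MetaProgram, core_frac: float = 0.25) -> set[str]:
    """Genes recurring in >= ceil(core_frac * m) member programs across >= 2 samples."""
    m = len(mp.members)
    threshold = int(np.ceil(core_frac * m))
    out = set()
    for g in mp.gene_union:
        hits = [p for p in mp.members if g in p.gene_set]
        if len(hits) >= threshold and len({p.sample_id for p in hits}) >= 2:
            out.add(g)
    return out


def discover_programs(
    nm_by_sample: dict[str, NormMatrix],
    malignant_masks: dict[str, np.ndarray],
    k_range: Sequence[int] = range(6, 10),
    top_n: int = 50,
    robust_overlap: int = 35,
    min_cells: int = 20,
    seed: int = 0,
    gene_subset: Optional[Sequence[str]] = None,
) -> dict[str, list[ExpressionProgram]]:
    """Per-sample NMF across ranks, returning the robust programs of each sample."""
    out: dict[str, list[ExpressionProgram]] = {}
    for sid, nm in nm_by_sample.items():
        if gene_subset is not None:
            keep = nm.genes["gene_id"].isin(set(gene_subset)).to_numpy()
            nm = NormMatrix(values=nm.values[np.flatnonzero(keep), :],
                            genes=nm.genes[keep].reset_index(drop=True),
                            barcodes=nm.barcodes, sample_id=nm.sample_id,
                            patient_id=nm.patient_id, clinical_group=nm.clinical_group,
                            cell_labels=nm.cell_labels, scale_factor=nm.scale_factor)
        Z, gene_ids = prepare_matrix(nm, malignant_masks.get(sid), min_cells=min_cells)
        if Z is None or len(gene_ids) < top_n:
            continue
        programs: list[ExpressionProgram] = []
        for k in k_range:
            if k >= min(Z.shape):
                continue
            W, _ = run_nmf(Z, k, seed=seed)
            programs.extend(extract_programs(W, gene_ids, sid, k, top_n=top_n))
        out[sid] = robust_programs(programs, robust_overlap=robust_overlap)
    return out


def find_metaprograms(
    robust_by_sample: dict[str, list[ExpressionProgram]],
    group_of_sample: dict[str, str],
    top_n: int = 50,
    robust_overlap: int = 35,
    core_frac: float = 0.25,
) -> dict[str, list[MetaProgram]]:
    """Cluster the GG and solid program pools separately into meta-programs."""
    out: dict[str, list[MetaProgram]] = {}
    for group in sorted({g for g in group_of_sample.values() if g != "nLung"}):
        pool = [p for sid, progs in robust_by_sample.items()
                for p in progs if group_of_sample.get(sid) == group]
        metas, _ = cluster_programs(pool, top_n=top_n, robust_overlap=robust_overlap,
                                    core_frac=core_frac)
        out[group] = metas
    return out


def match_metaprograms(
    metas_a: Sequence[MetaProgram], metas_b: Sequence[MetaProgram]
) -> list[tuple[int, int, float]]:
    """Greedy matching of two meta-program pools by core-gene Jaccard (for reporting)."""
    pairs = []
    for i, a in enumerate(metas_a):
        for j, b in enumerate(metas_b):
            u = a.core_genes | b.core_genes
            jac = len(a.core_genes & b.core_genes) / len(u) if u else 0.0
            pairs.append((jac, i, j))
    pairs.sort(reverse=True)
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for jac, i, j in pairs:
        if jac > 0 and i not in used_a and j not in used_b:
            matches.append((i, j, jac))
            used_a.add(i)
            used_b.add(j)
    return matches


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = sch.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
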