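"""Per-cell gene-signature scores with expression-bin-matched background correction.

A signature score is the mean normalized expression of the set's genes minus
the mean of a random background: for every signature gene, 100 genes are drawn
from the same of 25 equal-count expression bins (genes binned by their mean
normalized expression over all cells), excluding the signature itself.  The
subtraction removes the library-depth/complexity component shared by the cell,
so scores are comparable across cells and samples.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .qc import NormMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; duplicate symbols are removed, order preserved."""

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes: Sequence[str]):
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(g, None)
        if not seen:
            raise ValueError(f"gene set {name!r} is empty")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", tuple(seen))


@dataclass
class SignatureScore:
    name: str
    scores: np.ndarray              # per cell
    n_bins: int
    n_background: int
    seed: int
    genes_used: tuple[str, ...] = ()


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT: name <tab> description <tab> gene1 <tab> ..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], [g for g in parts[2:] if g]))
    return sets


def _set_rng(seed: int, name: str) -> np.random.Generator:
    """Independent stream per (seed, set name): adding a set never perturbs others."""
    digest = hashlib.sha256(name.encode()).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *words]))


def expression_bins(mean_expr: np.ndarray, gene_ids: Sequence[str],
                    n_bins: int = 25) -> np.ndarray:
    """Equal-count bin index per gene by mean expression (gene-id tiebreak)."""
    n = len(mean_expr)
    order = sorted(range(n), key=lambda i: (mean_expr[i], gene_ids[i]))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def score_gene_set(
    nm: NormMatrix,
    gs: GeneSet,
    n_bins: int = 25,
    n_background: int = 100,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> SignatureScore:
    """Background-corrected signature score per cell.

    score(c) = mean over set genes of expr(g, c)
             - mean over the pooled bin-matched background of expr(b, c)

    Background genes are drawn per signature gene from its expression bin,
    excluding signature members (without replacement when the bin is large
    enough, with replacement otherwise).  Missing signature genes are dropped
    with a warning; an entirely absent set is an error.
    """
    gene_ids = list(nm.genes["gene_id"])
    symbols = list(nm.genes["symbol"])
    pos = {g: i for i, g in enumerate(gene_ids)}
    for i, s in enumerate(symbols):
        pos.setdefault(s, i)

    fg = [pos[g] for g in gs.genes if g in pos]
    missing = [g for g in gs.genes if g not in pos]
    if missing:
        logger.warning("set %s: %d genes absent from matrix", gs.name, len(missing))
    if not fg:
        raise ValueError(f"no genes of set {gs.name!r} present in the matrix")
    fg = sorted(set(fg))

    X = sp.csr_matrix(nm.values)
    mean_expr = np.asarray(X.mean(axis=1)).ravel()
    bins = expression_bins(mean_expr, gene_ids, n_bins=n_bins)

    if rng is None:
        rng = _set_rng(seed, gs.name)
    fg_set = set(fg)
    background: list[np.ndarray] = []
    all_candidates = np.array([i for i in range(len(gene_ids)) if i not in fg_set])
    if all_candidates.size == 0:
        # the set covers every gene: it is its own background population
        all_candidates = np.arange(len(gene_ids))
    for g in fg:
        candidates = np.flatnonzero(bins == bins[g])
        candidates = candidates[~np.isin(candidates, list(fg_set))]
        if candidates.size == 0:
            logger.warning("set %s: bin of gene %s holds only set members; "
                           "sampling from all non-set genes", gs.name, gene_ids[g])
            candidates = all_candidates
        replace = candidates.size < n_background
        background.append(rng.choice(candidates, size=n_background, replace=replace))
    bg = np.concatenate(background)

    fg_mean = np.asarray(X[fg, :].mean(axis=0)).ravel()
    # pooled background mean honours sampling multiplicity
    bg_idx, counts = np.unique(bg, return_counts=True)
    bg_mean = np.asarray(
        X[bg_idx, :].T.dot(counts.astype(float))
    ).ravel() / bg.size
    return SignatureScore(
        name=gs.name, scores=fg_mean - bg_mean, n_bins=n_bins,
        n_background=n_background, seed=seed,
        genes_used=tuple(gene_ids[i] for i in fg),
    )


def score_named_sets(
    nm: NormMatrix,
    sets: Sequence[GeneSet],
    n_bins: int = 25,
    n_background: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score many sets; per-set random streams make results order-independent.

    Per-set failures (e.g. a set entirely absent) are logged and skipped;
    remaining sets are still scored.  Returns a cells x sets DataFrame.
    """
    out = {}
    for gs in sets:
        try:
            ss = score_gene_set(nm, gs, n_bins=n_bins, n_background=n_background,
                                seed=seed)
        except ValueError as exc:
            logger.error("skipping set %s: %s", gs.name, exc)
            continue
        out[gs.name] = ss.scores
    return pd.DataFrame(out, index=nm.barcodes)
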