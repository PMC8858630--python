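"""Ligand-receptor communication scores between cell groups with permutation tests.

The communication probability between a sender and a receiver cell group for a
ligand-receptor pair is a Hill function of the product of (i) the sender-group
mean of the per-cell geometric mean over ligand subunits and (ii) the
receiver-group mean over receptor subunits:

    prob = L*R / (Kh + L*R),   Kh = 0.5 by default.

Significance is assessed by a one-sided permutation test in which the cell
group labels are shuffled globally and all probabilities recomputed;
p = (1 + #{permuted >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .qc import NormMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LRPair:
    """A ligand-receptor pair; multi-subunit complexes are allowed on either side."""

    ligand: tuple[str, ...]
    receptor: tuple[str, ...]
    pathway: str = ""

    def __post_init__(self):
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor gene lists must be non-empty")

    @property
    def name(self) -> str:
        return ";".join(self.ligand) + "->" + ";".join(self.receptor)


def read_lr_table(path) -> list[LRPair]:
    """TSV with columns pathway, ligand (';'-joined subunits), receptor."""
    tab = pd.read_csv(path, sep="\t")
    return [
        LRPair(ligand=tuple(str(r["ligand"]).split(";")),
               receptor=tuple(str(r["receptor"]).split(";")),
               pathway=str(r.get("pathway", "")))
        for _, r in tab.iterrows()
    ]


def _subunit_geomean(nm: NormMatrix, genes: Sequence[str]) -> Optional[np.ndarray]:
    """Per-cell geometric mean of normalized expression over subunits; None if absent."""
    pos = {g: i for i, g in enumerate(nm.genes["gene_id"])}
    for i, s in enumerate(nm.genes["symbol"]):
        pos.setdefault(s, i)
    idx = []
    for g in genes:
        if g not in pos:
            return None
        idx.append(pos[g])
    X = np.asarray(sp.csr_matrix(nm.values)[idx, :].todense())
    return np.exp(np.log(np.maximum(X, 0.0) + 1e-300).mean(axis=0)) * (X > 0).all(axis=0)


def communication_probability(
    nm: NormMatrix,
    labels: Sequence[str],
    pair: LRPair,
    sender: str,
    receiver: str,
    hill_constant: float = 0.5,
    min_cells: int = 10,
) -> tuple[float, str]:
    """Hill-function communication probability; returns (probability, flag).

    Flags: "" (ok), "gene-missing" (pair gene absent, probability 0),
    "group-too-small" (sender or receiver below ``min_cells``, probability NaN).
    """
    labels = np.asarray(labels)
    smask = labels == sender
    rmask = labels == receiver
    if smask.sum() < min_cells or rmask.sum() < min_cells:
        return float("nan"), "group-too-small"
    lig = _subunit_geomean(nm, pair.ligand)
    rec = _subunit_geomean(nm, pair.receptor)
    if lig is None or rec is None:
        return 0.0, "gene-missing"
    L = float(lig[smask].mean())
    R = float(rec[rmask].mean())
    lr = L * R
    return lr / (hill_constant + lr), ""


def permutation_test(
    nm: NormMatrix,
    labels: Sequence[str],
    pairs: Sequence[LRPair],
    sender_receiver: Optional[Sequence[tuple[str, str]]] = None,
    n_perm: int = 999,
    seed: int = 0,
    hill_constant: float = 0.5,
    min_cells: int = 10,
) -> pd.DataFrame:
    """One-sided permutation test for every (sender, receiver, pair) combination.

    A single shared permutation stream (cell labels shuffled globally once per
    permutation) serves all pairs.  Observed probability 0 gives p = 1 by
    convention, flagged "zero-observed".
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    types = sorted(pd.unique(labels))
    if sender_receiver is None:
        sender_receiver = [(s, r) for s in types for r in types if s != r]

    # expression vectors are permutation-invariant: compute once per pair side
    lig_vecs = {p.name: _subunit_geomean(nm, p.ligand) for p in pairs}
    rec_vecs = {p.name: _subunit_geomean(nm, p.receptor) for p in pairs}

    def probs_for(lab: np.ndarray) -> dict[tuple[str, str, str], float]:
        masks = {t: lab == t for t in types}
        out = {}
        for s, r in sender_receiver:
            ns, nr = masks[s].sum(), masks[r].sum()
            for p in pairs:
                key = (s, r, p.name)
                if ns < min_cells or nr < min_cells:
                    out[key] = float("nan")
                    continue
                lig, rec = lig_vecs[p.name], rec_vecs[p.name]
                if lig is None or rec is None:
                    out[key] = 0.0
                    continue
                lr = float(lig[masks[s]].mean()) * float(rec[masks[r]].mean())
                out[key] = lr / (hill_constant + lr)
        return out

    observed = probs_for(labels)
    rng = np.random.default_rng(seed)
    exceed = {k: 0 for k in observed}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        pp = probs_for(perm)
        for k, v in pp.items():
            if not np.isnan(v) and not np.isnan(observed[k]) and v >= observed[k]:
                exceed[k] += 1

    rows = []
    for (s, r), p in ((sr, pr) for sr in sender_receiver for pr in pairs):
        key = (s, r, p.name)
        obs = observed[key]
        flag = ""
        if np.isnan(obs):
            pval = float("nan")
            flag = "group-too-small"
        elif obs == 0.0:
            pval = 1.0
            flag = "zero-observed"
        else:
            pval = (1 + exceed[key]) / (1 + n_perm)
        rows.append({"sender": s, "receiver": r, "pair": p.name,
                     "pathway": p.pathway, "probability": obs, "p": pval,
                     "flag": flag})
    return pd.DataFrame(rows)
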