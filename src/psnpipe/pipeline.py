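"""End-to-end orchestration: QC -> normalization -> labels -> CNV/malignant
calling -> NMF meta-programs -> signature scores -> group statistics ->
ligand-receptor communication, with per-stage logging and TSV outputs.

Gene filtering precedes cell filtering (genes detected in < 5 cells are
dropped at load, then the cell-quality criteria are applied), matching the
order the upstream toolchain imposes.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import cnv, comm, metaprograms, qc, signatures, stats
from .io import CountMatrix, RunConfig, read_mtx_triplet
from .qc import NormMatrix

logger = logging.getLogger(__name__)

IMMUNE_TYPES = ("T", "B", "NK", "myeloid")
REFERENCE_TYPES = ("epithelial", "T", "endothelial", "fibroblast")


@dataclass
class StageRecord:
    name: str
    n_cells_in: int
    n_cells_out: int
    seconds: float
    detail: str = ""


@dataclass
class RunReport:
    stages: list[StageRecord] = field(default_factory=list)
    outputs: dict[str, Path] = field(default_factory=dict)

    def log_stage(self, name: str, n_in: int, n_out: int, t0: float,
                  detail: str = "") -> None:
        rec = StageRecord(name, n_in, n_out, time.perf_counter() - t0, detail)
        self.stages.append(rec)
        logger.info("stage=%s cells_in=%d cells_out=%d wall=%.2fs %s",
                    name, n_in, n_out, rec.seconds, detail)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stages])


def fallback_clustering(nm_list: Sequence[NormMatrix], n_pcs: int = 30,
                        n_clusters: int = 8, seed: int = 0) -> list[pd.Series]:
    """Plumbing-only label fallback: pooled PCA + seeded k-means.

    Used only when no cell labels are supplied; a declared stand-in for graph
    clustering, producing anonymous cluster labels "cluster<k>".
    """
    X = np.hstack([np.asarray(nm.values.todense()) for nm in nm_list]).T
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(pcs)
    labels = pd.Series([f"cluster{c}" for c in km.labels_])
    out = []
    start = 0
    for nm in nm_list:
        out.append(labels.iloc[start:start + nm.n_cells].reset_index(drop=True))
        start += nm.n_cells
    return out


class StageError(RuntimeError):
    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on sample {sample!r}: {cause}")
        self.stage, self.sample = stage, sample


def run_pipeline(
    config: RunConfig,
    sample_dirs: Sequence,
    outdir,
    gene_sets: Sequence[signatures.GeneSet] = (),
    lr_pairs: Sequence[comm.LRPair] = (),
    marker_table: Optional[Mapping[str, Sequence[str]]] = None,
    labels_override: Optional[Mapping[str, pd.Series]] = None,
) -> RunReport:
    """Run every stage on the given sample directories and write TSV outputs.

    Cell labels come from per-sample ``cell_labels.tsv`` files, the
    ``labels_override`` mapping, or the PCA/k-means fallback, in that order of
    preference.  Fully reproducible from config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    # ---- read -------------------------------------------------------------
    t0 = time.perf_counter()
    raw: list[CountMatrix] = []
    for d in sample_dirs:
        try:
            raw.append(read_mtx_triplet(d))
        except Exception as exc:
            raise StageError("read", str(d), exc) from exc
    total_in = sum(m.n_cells for m in raw)
    report.log_stage("read", total_in, total_in, t0, f"samples={len(raw)}")

    # ---- QC: genes then cells --------------------------------------------
    t0 = time.perf_counter()
    filtered: list[CountMatrix] = []
    qc_rows = []
    for m in raw:
        try:
            mg, gsum = qc.filter_genes(m, config.gene_min_cells)
            mc, csum = qc.filter_cells(mg, config.min_genes, config.max_genes,
                                       config.max_mito_frac, config.max_umis)
        except Exception as exc:
            raise StageError("qc", m.sample_id, exc) from exc
        filtered.append(mc)
        for df in (gsum.to_frame(), csum.to_frame()):
            df.insert(0, "sample", m.sample_id)
            qc_rows.append(df)
    qc_table = pd.concat(qc_rows, ignore_index=True)
    qc_table = qc_table[(qc_table["cells_removed"] > 0) | (qc_table["genes_removed"] > 0)
                        | True]
    qc_table.to_csv(outdir / "qc_summary.tsv", sep="\t", index=False)
    report.outputs["qc_summary"] = outdir / "qc_summary.tsv"
    report.log_stage("qc", total_in, sum(m.n_cells for m in filtered), t0)

    # ---- normalization ----------------------------------------------------
    t0 = time.perf_counter()
    norms = [qc.lognormalize(m, config.scale_factor) for m in filtered]
    var_genes = set()
    for m in filtered:
        var_genes.update(qc.select_variable_genes(m, config.n_variable_genes))
    report.log_stage("normalize", sum(n.n_cells for n in norms),
                     sum(n.n_cells for n in norms), t0,
                     f"variable_genes={len(var_genes)}")

    # ---- labels -----------------------------------------------------------
    t0 = time.perf_counter()
    if labels_override is not None:
        for nm in norms:
            nm.cell_labels = labels_override[nm.sample_id].reset_index(drop=True)
    missing = [nm for nm in norms if nm.cell_labels is None]
    if missing:
        fallback = fallback_clustering(missing, config.n_pcs, config.n_clusters,
                                       config.seed)
        for nm, lab in zip(missing, fallback):
            nm.cell_labels = lab
    doublet_total = 0
    if marker_table:
        for i, nm in enumerate(norms):
            flags = qc.flag_doublets(nm, marker_table)
            doublet_total += int(flags.sum())
            if flags.any():
                norms[i] = nm.subset_cells(~flags)
                filtered[i] = filtered[i].subset_cells(~flags)
    norms = [nm for nm in norms if nm.n_cells > 0]
    report.log_stage("labels", sum(n.n_cells for n in norms) + doublet_total,
                     sum(n.n_cells for n in norms), t0,
                     f"doublets_removed={doublet_total}")

    # ---- CNV / malignant calling per patient ------------------------------
    t0 = time.perf_counter()
    malignant_masks: dict[str, np.ndarray] = {
        nm.sample_id: np.zeros(nm.n_cells, dtype=bool) for nm in norms}
    call_rows = []
    patients = sorted({nm.patient_id for nm in norms})
    for pat in patients:
        tumour = [nm for nm in norms
                  if nm.patient_id == pat and nm.clinical_group in ("GG", "solid")]
        if not tumour:
            continue
        try:
            pooled = _pool_norm(tumour)
            labels = pooled.cell_labels.to_numpy()
            reference = np.isin(labels, REFERENCE_TYPES)
            if not reference.any():
                logger.warning("patient %s: no reference cells; skipped", pat)
                continue
            profile, ref_vec, call = cnv.call_malignant_cells(
                pooled, reference, window=config.cnv_window, clip=config.cnv_clip,
                top_frac=config.cnv_top_frac, r_threshold=config.cnv_r_threshold)
        except Exception as exc:
            raise StageError("cnv", pat, exc) from exc
        offset = 0
        for nm in tumour:
            mask = call.malignant[offset:offset + nm.n_cells]
            epithelial_like = nm.cell_labels.isin(["epithelial", "malignant"]).to_numpy()
            malignant_masks[nm.sample_id] = mask & epithelial_like
            offset += nm.n_cells
        frame = call.to_frame()
        frame["patient"] = pat
        frame["score"] = cnv.cnv_cell_score(profile)
        call_rows.append(frame)
    if call_rows:
        pd.concat(call_rows, ignore_index=True).to_csv(
            outdir / "malignant_calls.tsv", sep="\t", index=False)
        report.outputs["malignant_calls"] = outdir / "malignant_calls.tsv"
    n_mal = int(sum(m.sum() for m in malignant_masks.values()))
    report.log_stage("cnv", sum(n.n_cells for n in norms), n_mal, t0,
                     f"malignant={n_mal}")

    # ---- NMF meta-programs -------------------------------------------------
    t0 = time.perf_counter()
    nm_by_sample = {nm.sample_id: nm for nm in norms
                    if nm.clinical_group in ("GG", "solid")}
    robust = metaprograms.discover_programs(
        nm_by_sample, malignant_masks, k_range=config.k_range,
        top_n=config.nmf_top_n, robust_overlap=config.nmf_robust_overlap,
        min_cells=config.nmf_min_cells, seed=config.seed,
        gene_subset=sorted(var_genes) if var_genes else None)
    group_of = {sid: nm.clinical_group for sid, nm in nm_by_sample.items()}
    metas = metaprograms.find_metaprograms(
        robust, group_of, top_n=config.nmf_top_n,
        robust_overlap=config.nmf_robust_overlap, core_frac=config.nmf_core_frac)
    prog_rows = []
    for sid, progs in robust.items():
        for p in progs:
            for rank, (g, s) in enumerate(zip(p.genes, p.scores), start=1):
                prog_rows.append({"sample": sid, "k": p.k, "factor": p.factor_index,
                                  "rank": rank, "gene": g, "score": s})
    pd.DataFrame(prog_rows).to_csv(outdir / "programs.tsv", sep="\t", index=False)
    meta_rows = []
    for grp, mlist in metas.items():
        for i, mp in enumerate(mlist):
            meta_rows.append({"group": grp, "metaprogram": f"{grp}_MP{i+1}",
                              "members": ",".join(p.name for p in mp.members),
                              "core_genes": ",".join(sorted(mp.core_genes))})
    pd.DataFrame(meta_rows).to_csv(outdir / "metaprograms.tsv", sep="\t", index=False)
    report.outputs["programs"] = outdir / "programs.tsv"
    report.outputs["metaprograms"] = outdir / "metaprograms.tsv"
    report.log_stage("metaprograms", n_mal, n_mal, t0,
                     f"robust={sum(len(v) for v in robust.values())} "
                     f"metas={sum(len(v) for v in metas.values())}")

    # ---- signature scores ---------------------------------------------------
    # scored on the pooled cohort so expression bins (and hence the matched
    # background) are shared across samples; per-sample binning would absorb
    # the very group-level shifts the mixed model is meant to test
    t0 = time.perf_counter()
    score_frames = []
    if gene_sets:
        pooled = _pool_norm(norms)
        tab = signatures.score_named_sets(
            pooled, gene_sets, n_bins=config.sig_n_bins,
            n_background=config.sig_n_background, seed=config.seed)
        tab.insert(0, "sample", np.repeat([nm.sample_id for nm in norms],
                                          [nm.n_cells for nm in norms]))
        tab.insert(1, "patient", np.repeat([nm.patient_id for nm in norms],
                                           [nm.n_cells for nm in norms]))
        tab.insert(2, "group", np.repeat([nm.clinical_group for nm in norms],
                                         [nm.n_cells for nm in norms]))
        score_frames.append(tab)
        tab.to_csv(outdir / "signature_scores.tsv", sep="\t")
        report.outputs["signature_scores"] = outdir / "signature_scores.tsv"
    report.log_stage("signatures", sum(n.n_cells for n in norms),
                     sum(n.n_cells for n in norms), t0,
                     f"sets={len(gene_sets)}")

    # ---- composition + group statistics -------------------------------------
    t0 = time.perf_counter()
    label_rows = pd.concat([
        pd.DataFrame({"sample": nm.sample_id, "cell_type": nm.cell_labels})
        for nm in norms], ignore_index=True)
    meta = pd.DataFrame([{"sample_id": nm.sample_id, "patient_id": nm.patient_id,
                          "clinical_group": nm.clinical_group} for nm in norms])
    present_types = set(label_rows["cell_type"])
    denom = [t for t in IMMUNE_TYPES if t in present_types] or sorted(present_types)
    comp = stats.composition_table(label_rows, meta, denom)
    comp.to_csv(outdir / "composition.tsv", sep="\t")
    groups_present = set(comp["clinical_group"])
    test_frames = []
    if {"nLung", "GG"} <= groups_present:
        test_frames.append(stats.compare_composition_groups(comp, "nLung", "GG"))
    if {"nLung", "solid"} <= groups_present:
        test_frames.append(stats.compare_composition_groups(comp, "nLung", "solid"))
    if {"GG", "solid"} <= groups_present:
        test_frames.append(stats.compare_composition_groups(comp, "GG", "solid",
                                                            paired=True))
    if test_frames:
        pd.concat(test_frames, ignore_index=True).to_csv(
            outdir / "tests.tsv", sep="\t", index=False)
        report.outputs["tests"] = outdir / "tests.tsv"
    if score_frames:
        scores_all = pd.concat(score_frames)
        score_cols = [c for c in scores_all.columns
                      if c not in ("sample", "patient", "group")]
        lmm = stats.lmm_group_comparison(
            scores_all[score_cols], scores_all["group"], scores_all["patient"],
            comparisons=[(a, b) for a, b in
                         [("GG", "solid"), ("nLung", "GG"), ("nLung", "solid")]
                         if {a, b} <= groups_present])
        lmm.to_csv(outdir / "lmm.tsv", sep="\t", index=False)
        report.outputs["lmm"] = outdir / "lmm.tsv"
    report.outputs["composition"] = outdir / "composition.tsv"
    report.log_stage("group_stats", len(label_rows), len(label_rows), t0)

    # ---- ligand-receptor communication --------------------------------------
    t0 = time.perf_counter()
    if lr_pairs:
        pooled = _pool_norm(norms)
        lr = comm.permutation_test(
            pooled, pooled.cell_labels.to_numpy(), lr_pairs,
            n_perm=config.n_permutations, seed=config.seed,
            hill_constant=config.lr_hill_constant, min_cells=config.lr_min_cells)
        lr.to_csv(outdir / "lr_results.tsv", sep="\t", index=False)
        report.outputs["lr_results"] = outdir / "lr_results.tsv"
    report.log_stage("communication", sum(n.n_cells for n in norms),
                     sum(n.n_cells for n in norms), t0,
                     f"pairs={len(lr_pairs)}")

    report.to_frame().to_csv(outdir / "run_report.tsv", sep="\t", index=False)
    report.outputs["run_report"] = outdir / "run_report.tsv"
    return report


def _pool_norm(norms: Sequence[NormMatrix]) -> NormMatrix:
    """Column-concatenate samples sharing a gene universe (intersecting genes)."""
    if len(norms) == 1:
        nm = norms[0]
        return NormMatrix(values=nm.values, genes=nm.genes,
                          barcodes=[f"{nm.sample_id}:{b}" for b in nm.barcodes],
                          sample_id=nm.sample_id, patient_id=nm.patient_id,
                          clinical_group=nm.clinical_group,
                          cell_labels=nm.cell_labels, scale_factor=nm.scale_factor)
    common = set(norms[0].genes["gene_id"])
    for nm in norms[1:]:
        common &= set(nm.genes["gene_id"])
    ref = norms[0].genes[norms[0].genes["gene_id"].isin(common)]
    blocks = []
    barcodes = []
    labels = []
    import scipy.sparse as sp
    for nm in norms:
        pos = {g: i for i, g in enumerate(nm.genes["gene_id"])}
        idx = [pos[g] for g in ref["gene_id"]]
        blocks.append(nm.values[idx, :])
        barcodes.extend(f"{nm.sample_id}:{b}" for b in nm.barcodes)
        if nm.cell_labels is not None:
            labels.extend(nm.cell_labels)
    values = sp.hstack(blocks).tocsr()
    return NormMatrix(
        values=values, genes=ref.reset_index(drop=True), barcodes=barcodes,
        sample_id="pooled", patient_id=norms[0].patient_id,
        clinical_group="pooled",
        cell_labels=pd.Series(labels) if labels else None,
        scale_factor=norms[0].scale_factor)
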