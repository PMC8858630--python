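"""Synthetic multi-patient scRNA-seq cohort with planted ground truth.

The generator emulates a three-group lung cohort — normal lung (nLung) plus
paired ground-glass (GG) and solid tumour components per patient — at desk
scale.  Counts are negative-binomial (gamma-Poisson) draws around cell-wise
means

    mean = libsize * softmax(log baseline(type)
                             + CNV log-fold (malignant cells, planted segments)
                             + sum_p activity(cell, p) * loading(p)
                             + group-level signature shifts),

with a fixed fraction of each cell's library allocated to mitochondrial
("MT-") genes.  Planted structure covers every downstream stage: chromosomal
CNV segments carried by the malignant cell type, cross-sample expression
programs with a two-component (off/on) activity mixture, group-specific
signature shifts, group-specific cell-type abundances, and low-quality cells
that trip each QC rule exactly.  All randomness flows from one integer seed
through a single `numpy` SeedSequence tree; identical config + seed
reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io import CountMatrix, write_mtx_triplet

logger = logging.getLogger(__name__)

QC_CLASSES = ("none", "low_genes", "high_genes", "high_mito", "high_umi")


@dataclass
class CellTypeSpec:
    name: str
    markers: tuple[str, ...]
    group_weights: dict[str, float]      # abundance weight per clinical group
    marker_boost: float = 3.0
    baseline: Optional[np.ndarray] = None  # optional explicit log-mean vector


@dataclass
class CnvSegmentSpec:
    chromosome: str
    start_frac: float                    # fractional position range on the chromosome
    end_frac: float
    fold: float                          # multiplicative fold-change, > 0
    carrier: str = "malignant"


@dataclass
class ProgramSpec:
    name: str
    genes: tuple[str, ...]               # exactly 50 distinct genes
    on_prob: float = 0.35                # fraction of carrier cells with the program on
    activity: float = 1.2                # mean log-scale activity of "on" cells


@dataclass
class SignatureShiftSpec:
    name: str
    genes: tuple[str, ...]
    group: str
    shift: float                         # additive log-mean shift


@dataclass
class QcContaminantFractions:
    low_genes: float = 0.0
    high_genes: float = 0.0
    high_mito: float = 0.0
    high_umi: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in QC_CLASSES[1:]}


@dataclass
class CohortConfig:
    n_patients: int = 12
    n_nlung_patients: int = 5
    groups_per_patient: tuple[str, ...] = ("nLung", "GG", "solid")
    n_cells_per_sample: int = 300
    n_genes: int = 1000
    n_chromosomes: int = 10
    n_mito_genes: int = 13
    cell_type_spec: tuple[CellTypeSpec, ...] = ()
    cnv_spec: tuple[CnvSegmentSpec, ...] = ()
    program_spec: tuple[ProgramSpec, ...] = ()
    signature_shift_spec: tuple[SignatureShiftSpec, ...] = ()
    qc_contaminant_fractions: QcContaminantFractions = field(
        default_factory=QcContaminantFractions)
    libsize_lognormal_params: tuple[float, float] = (np.log(2000.0), 0.35)
    nb_dispersion: float = 0.3
    mito_frac: float = 0.05
    seed: int = 0

    def validate(self, gene_ids: Optional[Sequence[str]] = None) -> None:
        if min(self.n_patients, self.n_cells_per_sample, self.n_genes,
               self.n_chromosomes) <= 0:
            raise ValueError("all counts must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for seg in self.cnv_spec:
            if seg.fold <= 0:
                raise ValueError(f"fold-change must be > 0 (segment on {seg.chromosome})")
        for t in self.cell_type_spec:
            for g, w in t.group_weights.items():
                if w < 0:
                    raise ValueError(f"negative abundance weight for {t.name} in {g}")
        for g in ("nLung", "GG", "solid"):
            tot = sum(t.group_weights.get(g, 0.0) for t in self.cell_type_spec)
            if self.cell_type_spec and g in self.groups_per_patient and not np.isclose(tot, 1.0):
                raise ValueError(f"abundance weights for group {g} sum to {tot}, not 1")
        for p in self.program_spec:
            if len(set(p.genes)) != 50:
                raise ValueError(f"program {p.name} must list exactly 50 distinct genes")
            if gene_ids is not None:
                unknown = set(p.genes) - set(gene_ids)
                if unknown:
                    raise ValueError(
                        f"program {p.name} references unknown genes: {sorted(unknown)[:5]}")
        fr = self.qc_contaminant_fractions
        if sum(fr.as_dict().values()) > 0.5:
            raise ValueError("QC contaminant fractions exceed half the cells")
        if fr.high_genes > 0 and self.n_genes <= 6000:
            raise ValueError("planting high_genes cells requires n_genes > 6000")


@dataclass
class GroundTruth:
    """Planted truth per cell and per gene, plus the generating config."""

    cells: pd.DataFrame     # cell, sample, patient, group, cell_type, malignant, qc_class, program_*
    genes: pd.DataFrame     # gene_id, chromosome, start, cnv_segment, cnv_fold
    config: CohortConfig


# ---------------------------------------------------------------------------
# gene universe and default configuration
# ---------------------------------------------------------------------------

def build_gene_table(config: CohortConfig) -> pd.DataFrame:
    """Deterministic gene table: autosome-like blocks plus an MT contig."""
    n_nuclear = config.n_genes - config.n_mito_genes
    per_chrom = [n_nuclear // config.n_chromosomes] * config.n_chromosomes
    for i in range(n_nuclear % config.n_chromosomes):
        per_chrom[i] += 1
    rows = []
    gi = 0
    for c, nc in enumerate(per_chrom, start=1):
        for j in range(nc):
            rows.append((f"G{gi:05d}", f"G{gi:05d}", str(c), 1000 * j))
            gi += 1
    for j in range(config.n_mito_genes):
        rows.append((f"MT-{j:02d}", f"MT-{j:02d}", "MT", 100 * j))
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "chromosome", "start"])


def _genes_on(gene_table: pd.DataFrame, chromosome: str,
              lo: float = 0.0, hi: float = 1.0) -> list[str]:
    sub = gene_table[gene_table["chromosome"] == chromosome]
    n = len(sub)
    lo_i, hi_i = int(np.floor(lo * n)), int(np.ceil(hi * n))
    return list(sub["gene_id"].iloc[lo_i:hi_i])


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default study conditions: 12 patients with paired GG/solid samples,
    nLung for 5 of them, 300 cells per sample over 1000 genes on 10 chromosomes.

    Cell-type abundances decline for myeloid/NK and rise for T/B/plasma-like
    types from nLung through GG to solid; the malignant type carries fold-2
    amplifications on chromosomes 1 and 2 and a fold-0.5 deletion on
    chromosome 3; three 50-gene expression programs are planted in malignant
    cells across all tumour samples; a "stress" signature is shifted up in the
    solid group.
    """
    base = CohortConfig(seed=seed)
    for k, v in overrides.items():
        setattr(base, k, v)
    gene_table = build_gene_table(base)

    def pick(chrom: str, start: int, n: int) -> tuple[str, ...]:
        ids = _genes_on(gene_table, chrom)
        return tuple(ids[start:start + n])

    marker_chrom = str(base.n_chromosomes)
    type_defs = [
        ("T",           {"nLung": 0.24, "GG": 0.28, "solid": 0.32}),
        ("B",           {"nLung": 0.06, "GG": 0.10, "solid": 0.13}),
        ("NK",          {"nLung": 0.13, "GG": 0.08, "solid": 0.05}),
        ("myeloid",     {"nLung": 0.26, "GG": 0.18, "solid": 0.12}),
        ("endothelial", {"nLung": 0.09, "GG": 0.06, "solid": 0.05}),
        ("fibroblast",  {"nLung": 0.07, "GG": 0.06, "solid": 0.05}),
        ("epithelial",  {"nLung": 0.15, "GG": 0.08, "solid": 0.06}),
        ("malignant",   {"nLung": 0.00, "GG": 0.16, "solid": 0.22}),
    ]
    cell_types = []
    for i, (name, weights) in enumerate(type_defs):
        # the malignant type shares the epithelial markers (it is epithelial-derived)
        midx = 6 if name == "malignant" else i
        cell_types.append(CellTypeSpec(
            name=name, markers=pick(marker_chrom, 5 * midx, 5), group_weights=weights))

    if "cell_type_spec" not in overrides:
        base.cell_type_spec = tuple(cell_types)
    if "cnv_spec" not in overrides:
        base.cnv_spec = (
            CnvSegmentSpec("1", 0.0, 0.6, 2.0),
            CnvSegmentSpec("2", 0.2, 0.9, 2.0),
            CnvSegmentSpec("3", 0.1, 0.5, 0.5),
        )
    # program and signature genes are interleaved across chromosomes 4-9:
    # real co-expression programs are genomically scattered (unlike CNV
    # segments), so they must not mimic contiguous copy-number blocks
    scatter_pool = [g for c in range(4, min(10, base.n_chromosomes))
                    for g in _genes_on(gene_table, str(c))]
    if "program_spec" not in overrides:
        base.program_spec = tuple(
            ProgramSpec(name=f"program{i+1}", genes=tuple(scatter_pool[i::12][:50]))
            for i in range(3)
        )
    if "signature_shift_spec" not in overrides:
        base.signature_shift_spec = (
            SignatureShiftSpec(name="stress", genes=tuple(scatter_pool[5::12][:30]),
                               group="solid", shift=0.7),
        )
    base.validate(gene_table["gene_id"])
    return base


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------

def _sample_list(config: CohortConfig) -> list[tuple[str, str]]:
    """(patient, group) pairs in deterministic order."""
    out = []
    for i in range(config.n_patients):
        pid = f"P{i+1:02d}"
        if "nLung" in config.groups_per_patient and i < config.n_nlung_patients:
            out.append((pid, "nLung"))
        for g in ("GG", "solid"):
            if g in config.groups_per_patient:
                out.append((pid, g))
    return out


class _Model:
    """Deterministic per-config model parameters derived from the seed."""

    def __init__(self, config: CohortConfig):
        self.config = config
        self.gene_table = build_gene_table(config)
        config.validate(self.gene_table["gene_id"])
        self.gene_pos = {g: i for i, g in enumerate(self.gene_table["gene_id"])}
        self.mito = self.gene_table["chromosome"].to_numpy() == "MT"
        self.nuclear = ~self.mito
        G = config.n_genes

        root = np.random.SeedSequence(config.seed)
        self.global_seed, self.sample_root = root.spawn(2)
        rng = np.random.default_rng(self.global_seed)

        shared = rng.normal(0.0, 1.5, G)
        # program genes are expressed genes (as real co-expression programs are):
        # floor their baseline so the planted block structure is detectable
        for prog in config.program_spec:
            idx = [self.gene_pos[g] for g in prog.genes]
            shared[idx] = np.maximum(shared[idx], 1.0)
        self.baselines = {}
        type_names = [t.name for t in config.cell_type_spec]
        perturb = {}
        for t in config.cell_type_spec:
            if t.name == "malignant" and "epithelial" in type_names:
                continue
            idx = rng.choice(np.flatnonzero(self.nuclear), size=min(50, G // 4),
                             replace=False)
            v = np.zeros(G)
            v[idx] = rng.normal(0.0, 1.0, idx.size)
            perturb[t.name] = v
        for t in config.cell_type_spec:
            if t.baseline is not None:
                self.baselines[t.name] = np.asarray(t.baseline, dtype=float)
                continue
            src = "epithelial" if (t.name == "malignant" and "epithelial" in perturb) else t.name
            b = shared + perturb[src]
            b = b.copy()
            for m in t.markers:
                b[self.gene_pos[m]] += t.marker_boost
            self.baselines[t.name] = b

        # CNV log-folds per gene for carrier types
        self.cnv_logfold = {}
        self.gene_segment = np.array([""] * G, dtype=object)
        self.gene_fold = np.ones(G)
        for si, seg in enumerate(config.cnv_spec):
            genes = _genes_on(self.gene_table, seg.chromosome, seg.start_frac, seg.end_frac)
            idx = np.array([self.gene_pos[g] for g in genes], dtype=int)
            lf = self.cnv_logfold.setdefault(seg.carrier, np.zeros(G))
            lf[idx] += np.log(seg.fold)
            self.gene_segment[idx] = f"segment{si+1}"
            self.gene_fold[idx] *= seg.fold

        # program loadings (nonzero on each program's 50 genes)
        self.loadings = np.zeros((len(config.program_spec), G))
        for pi, prog in enumerate(config.program_spec):
            idx = np.array([self.gene_pos[g] for g in prog.genes], dtype=int)
            self.loadings[pi, idx] = rng.uniform(0.5, 1.5, idx.size)

        # fixed mitochondrial composition profile
        if self.mito.any():
            w = rng.uniform(0.5, 1.5, int(self.mito.sum()))
            self.mito_profile = w / w.sum()
        else:
            self.mito_profile = np.zeros(0)

        self.shift_vectors = []
        for sh in config.signature_shift_spec:
            idx = np.array([self.gene_pos[g] for g in sh.genes], dtype=int)
            v = np.zeros(G)
            v[idx] = sh.shift
            self.shift_vectors.append((sh.group, v))

    def expected_probs(self, cell_type: str, group: str,
                       with_cnv: bool = True) -> np.ndarray:
        """Noise-free per-gene sampling probabilities for a cell of a type/group."""
        logm = self.baselines[cell_type].copy()
        if with_cnv and cell_type in self.cnv_logfold:
            logm = logm + self.cnv_logfold[cell_type]
        for g, v in self.shift_vectors:
            if g == group:
                logm = logm + v
        p = np.zeros(self.config.n_genes)
        nuc = self.nuclear
        e = np.exp(logm[nuc] - logm[nuc].max())
        p[nuc] = (1.0 - self.config.mito_frac) * e / e.sum()
        p[self.mito] = self.config.mito_frac * self.mito_profile
        return p


def _draw_labels(model: _Model, rng: np.random.Generator, group: str) -> np.ndarray:
    cfg = model.config
    w = np.array([t.group_weights.get(group, 0.0) for t in cfg.cell_type_spec])
    w = w / w.sum()
    return rng.choice(len(cfg.cell_type_spec), size=cfg.n_cells_per_sample, p=w)


def _plant_qc_classes(counts: np.ndarray, qc_class: np.ndarray, model: _Model,
                      rng: np.random.Generator) -> None:
    """Modify counts in place so each planted class trips exactly its QC rule."""
    cfg = model.config
    n = counts.shape[0]
    fr = cfg.qc_contaminant_fractions.as_dict()
    order = rng.permutation(n)
    cursor = 0
    mito = model.mito
    nuclear_idx = np.flatnonzero(model.nuclear)
    for cls in QC_CLASSES[1:]:
        k = int(round(fr[cls] * n))
        chosen = order[cursor:cursor + k]
        cursor += k
        qc_class[chosen] = cls
        for ci in chosen:
            row = counts[ci]
            if cls == "low_genes":
                nz = np.flatnonzero((row > 0) & model.nuclear)
                target = int(rng.integers(50, 150))
                keep = rng.choice(nz, size=min(target, nz.size), replace=False)
                new = np.zeros_like(row)
                new[keep] = row[keep]
                new[keep[:1]] += (new[keep[:1]] == 0)
                counts[ci] = new
            elif cls == "high_genes":
                extra = rng.choice(nuclear_idx, size=6100 + int(rng.integers(0, 300)),
                                   replace=False)
                row[extra] = np.maximum(row[extra], 1)
            elif cls == "high_mito":
                rest = row[~mito].sum()
                target_mito = int(np.ceil(rest / 3)) + 1      # frac > 0.25 > 0.15
                alloc = rng.multinomial(target_mito, model.mito_profile)
                row[mito] = alloc
            elif cls == "high_umi":
                total = row.sum()
                factor = int(np.ceil(60001 / max(total, 1))) + 1
                row *= factor


def _repair_clean_cells(counts: np.ndarray, qc_class: np.ndarray,
                        model: _Model, rng: np.random.Generator) -> None:
    """Nudge unplanted cells that trip a QC rule by chance back into compliance."""
    mito = model.mito
    for ci in np.flatnonzero(qc_class == "none"):
        row = counts[ci]
        for _ in range(5):
            detected = int((row > 0).sum())
            total = int(row.sum())
            mito_frac = row[mito].sum() / max(total, 1)
            if 200 <= detected <= 6000 and total <= 60000 and mito_frac <= 0.15:
                break
            if detected < 200:
                zeros = np.flatnonzero((row == 0) & model.nuclear)
                add = rng.choice(zeros, size=min(210 - detected, zeros.size),
                                 replace=False)
                row[add] = 1
            if detected > 6000:
                nz = np.flatnonzero((row > 0) & model.nuclear)
                drop = rng.choice(nz, size=detected - 5900, replace=False)
                row[drop] = 0
            if row.sum() > 60000:
                row //= 2
            if row[mito].sum() / max(row.sum(), 1) > 0.15:
                row[mito] //= 2


def _simulate_sample(model: _Model, rng: np.random.Generator, patient: str,
                     group: str, counts: bool = True):
    cfg = model.config
    n, G = cfg.n_cells_per_sample, cfg.n_genes
    type_idx = _draw_labels(model, rng, group)
    type_names = np.array([t.name for t in cfg.cell_type_spec])
    labels = type_names[type_idx]
    carriers = {seg.carrier for seg in cfg.cnv_spec}
    malignant = np.isin(labels, list(carriers))

    n_prog = len(cfg.program_spec)
    activities = np.zeros((n, n_prog))
    for pi, prog in enumerate(cfg.program_spec):
        on = (rng.random(n) < prog.on_prob) & malignant
        amp = np.abs(rng.normal(prog.activity, prog.activity / 4, n))
        activities[:, pi] = np.where(on, amp, 0.0)

    qc_class = np.array(["none"] * n, dtype=object)
    matrix = None
    if counts:
        logm = np.stack([model.baselines[t] for t in labels])
        for carrier, lf in model.cnv_logfold.items():
            logm[labels == carrier] += lf
        if n_prog:
            logm += activities @ model.loadings
        for g, v in model.shift_vectors:
            if g == group:
                logm += v

        nuc = model.nuclear
        z = logm[:, nuc] - logm[:, nuc].max(axis=1, keepdims=True)
        e = np.exp(z)
        P = np.zeros((n, G))
        P[:, nuc] = (1.0 - cfg.mito_frac) * e / e.sum(axis=1, keepdims=True)
        if model.mito.any():
            P[:, model.mito] = cfg.mito_frac * model.mito_profile

        mu_log, sigma = cfg.libsize_lognormal_params
        libsize = rng.lognormal(mean=mu_log, sigma=sigma, size=n)
        mean = libsize[:, None] * P
        lam = rng.gamma(shape=1.0 / cfg.nb_dispersion,
                        scale=mean * cfg.nb_dispersion)
        matrix = rng.poisson(lam).astype(np.int64)

        _plant_qc_classes(matrix, qc_class, model, rng)
        _repair_clean_cells(matrix, qc_class, model, rng)

    sample_id = f"{patient}_{group}"
    barcodes = [f"{sample_id}-C{i:05d}" for i in range(n)]
    cells = pd.DataFrame({
        "cell": [f"{sample_id}:{b}" for b in barcodes],
        "barcode": barcodes,
        "sample": sample_id,
        "patient": patient,
        "group": group,
        "cell_type": labels,
        "malignant": malignant,
        "qc_class": qc_class,
    })
    for pi, prog in enumerate(cfg.program_spec):
        cells[f"activity_{prog.name}"] = activities[:, pi]

    cm = None
    if counts:
        cm = CountMatrix(
            counts=sp.csr_matrix(matrix.T),
            genes=model.gene_table,
            barcodes=barcodes,
            sample_id=sample_id,
            patient_id=patient,
            clinical_group=group,
            cell_labels=pd.Series(labels),
        )
    return cm, cells


def simulate_cohort(config: CohortConfig,
                    counts: bool = True) -> tuple[list[CountMatrix], GroundTruth]:
    """Generate one :class:`CountMatrix` per (patient, group) sample plus truth.

    With ``counts=False`` only the cell-level ground truth (types, malignant
    flags, program activities) is drawn — the fast path for label-level
    replication studies such as composition power checks.
    """
    model = _Model(config)
    samples = _sample_list(config)
    child_seeds = model.sample_root.spawn(len(samples))
    matrices: list[CountMatrix] = []
    cell_frames = []
    for (patient, group), seed in zip(samples, child_seeds):
        rng = np.random.default_rng(seed)
        cm, cells = _simulate_sample(model, rng, patient, group, counts=counts)
        if cm is not None:
            matrices.append(cm)
        cell_frames.append(cells)
    genes = model.gene_table.copy()
    genes["cnv_segment"] = model.gene_segment
    genes["cnv_fold"] = model.gene_fold
    gt = GroundTruth(cells=pd.concat(cell_frames, ignore_index=True),
                     genes=genes, config=config)
    return matrices, gt


def expected_probs(config: CohortConfig, cell_type: str, group: str,
                   with_cnv: bool = True) -> np.ndarray:
    """Noise-free per-gene sampling probabilities (generator means / libsize)."""
    return _Model(config).expected_probs(cell_type, group, with_cnv=with_cnv)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def _config_to_dict(config: CohortConfig) -> dict:
    def convert(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, tuple):
            return [convert(v) for v in obj]
        if isinstance(obj, list):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj
    return convert(dataclasses.asdict(config))


def write_fixture(cohort: Sequence[CountMatrix], ground_truth: GroundTruth,
                  directory) -> Path:
    """Write per-sample MTX triplets plus cohort metadata and ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for cm in cohort:
        write_mtx_triplet(cm, directory / cm.sample_id)
        meta_rows.append({"sample_id": cm.sample_id, "patient_id": cm.patient_id,
                          "clinical_group": cm.clinical_group})
    pd.DataFrame(meta_rows).to_csv(directory / "samples.tsv", sep="\t", index=False)
    ground_truth.cells.to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    ground_truth.genes.to_csv(directory / "ground_truth_genes.tsv", sep="\t", index=False)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(ground_truth.config), fh, sort_keys=True)
    return directory


def fixture_checksum(directory) -> str:
    """SHA-256 over the sorted file contents of a fixture directory."""
    directory = Path(directory)
    h = hashlib.sha256()
    for path in sorted(directory.rglob("*")):
        if path.is_file():
            h.update(path.relative_to(directory).as_posix().encode())
            h.update(path.read_bytes())
    return h.hexdigest()
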