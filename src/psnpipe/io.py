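"""Count-matrix container, 10x-style MatrixMarket triplet I/O and run configuration.

The on-disk layout per sample is the Cell Ranger convention extended with gene
coordinates:

* ``matrix.mtx``   — MatrixMarket coordinate integer, genes x cells, 1-based
* ``genes.tsv``    — gene_id, symbol, chromosome, start (0-based), no header
* ``barcodes.tsv`` — one barcode per line
* ``samples.tsv``  — header row: sample_id, patient_id, clinical_group

Plain and gzip-compressed variants of each file are accepted.
"""

from __future__ import annotations

import dataclasses
import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

CLINICAL_GROUPS = ("nLung", "GG", "solid")

GENE_COLUMNS = ["gene_id", "symbol", "chromosome", "start"]


class FormatError(ValueError):
    """Raised when an on-disk triplet violates the expected format."""


def chromosome_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: 1..22, X, Y, then anything else lexicographically."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.isdigit():
        return (int(c), "")
    if c == "X":
        return (23, "")
    if c == "Y":
        return (24, "")
    return (25, c)


@dataclass
class CountMatrix:
    """Sparse gene x cell UMI count matrix with gene coordinates and sample metadata.

    Parameters
    ----------
    counts
        ``scipy.sparse`` matrix of shape (n_genes, n_cells) holding non-negative
        integer UMI counts.
    genes
        DataFrame with columns ``gene_id, symbol, chromosome, start`` (start is
        a 0-based position used only for ordering genes along the genome).
    barcodes
        Cell barcodes, unique within the sample.
    sample_id, patient_id, clinical_group
        Sample metadata; ``clinical_group`` is one of ``nLung``, ``GG``, ``solid``.
    cell_labels
        Optional per-cell cell-type labels (same length as ``barcodes``).
    """

    counts: sp.spmatrix
    genes: pd.DataFrame
    barcodes: list[str]
    sample_id: str = "sample"
    patient_id: str = "patient"
    clinical_group: str = "GG"
    cell_labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.genes = self.genes.reset_index(drop=True)
        self.barcodes = list(self.barcodes)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes:
            raise FormatError(
                f"gene table has {len(self.genes)} rows for a matrix with {n_genes} genes"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for a matrix with {n_cells} cells"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError(f"duplicate barcodes in sample {self.sample_id!r}")
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise FormatError(f"gene table missing columns {missing}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.cell_labels is not None and len(self.cell_labels) != n_cells:
            raise FormatError("cell_labels length does not match cell count")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    def genome_order(self) -> np.ndarray:
        """Indices sorting genes by (chromosome natural order, start, gene_id)."""
        keys = self.genes["chromosome"].map(chromosome_sort_key)
        order = sorted(
            range(self.n_genes),
            key=lambda i: (keys.iloc[i], int(self.genes["start"].iloc[i]),
                           self.genes["gene_id"].iloc[i]),
        )
        return np.asarray(order)

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        labels = None
        if self.cell_labels is not None:
            labels = self.cell_labels.iloc[idx].reset_index(drop=True)
        return CountMatrix(
            counts=self.counts[:, idx],
            genes=self.genes,
            barcodes=[self.barcodes[i] for i in idx],
            sample_id=self.sample_id,
            patient_id=self.patient_id,
            clinical_group=self.clinical_group,
            cell_labels=labels,
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[idx, :],
            genes=self.genes.iloc[idx],
            barcodes=self.barcodes,
            sample_id=self.sample_id,
            patient_id=self.patient_id,
            clinical_group=self.clinical_group,
            cell_labels=self.cell_labels,
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and self.genes.reset_index(drop=True).equals(other.genes.reset_index(drop=True))
            and self.barcodes == other.barcodes
            and self.sample_id == other.sample_id
            and self.patient_id == other.patient_id
            and self.clinical_group == other.clinical_group
        )


def _find(directory: Path, name: str) -> Path:
    for candidate in (directory / name, directory / (name + ".gz")):
        if candidate.exists():
            return candidate
    raise FormatError(f"missing {name}[.gz] in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_mtx_triplet(directory: os.PathLike | str) -> CountMatrix:
    """Read a 10x-style MTX triplet directory into a :class:`CountMatrix`.

    MTX 1-based indices are mapped to 0-based internal indices by the reader.
    Raises :class:`FormatError` naming the offending file on any dimension
    mismatch between the matrix header and the annotation files.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    genes_path = _find(directory, "genes.tsv")
    barcodes_path = _find(directory, "barcodes.tsv")

    with _open_text(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)

    with _open_text(genes_path) as fh:
        genes = pd.read_csv(fh, sep="\t", header=None, names=GENE_COLUMNS,
                            dtype={"chromosome": str})
    with _open_text(barcodes_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if len(genes) != mat.shape[0]:
        raise FormatError(
            f"{genes_path.name}: {len(genes)} genes but matrix header says {mat.shape[0]}"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{barcodes_path.name}: {len(barcodes)} barcodes but matrix header says {mat.shape[1]}"
        )

    meta = dict(sample_id=directory.name, patient_id=directory.name, clinical_group="GG")
    try:
        samples_path = _find(directory, "samples.tsv")
    except FormatError:
        samples_path = None
    if samples_path is not None:
        with _open_text(samples_path) as fh:
            samples = pd.read_csv(fh, sep="\t")
        row = samples.iloc[0]
        meta = dict(
            sample_id=str(row["sample_id"]),
            patient_id=str(row["patient_id"]),
            clinical_group=str(row["clinical_group"]),
        )

    labels = None
    for name in ("cell_labels.tsv", "cell_labels.tsv.gz"):
        p = directory / name
        if p.exists():
            with _open_text(p) as fh:
                tab = pd.read_csv(fh, sep="\t")
            labels = pd.Series(tab["cell_type"].values)
            break

    return CountMatrix(counts=mat, genes=genes, barcodes=barcodes,
                       cell_labels=labels, **meta)


def write_mtx_triplet(matrix: CountMatrix, directory: os.PathLike | str) -> Path:
    """Write a :class:`CountMatrix` as a plain-text MTX triplet directory.

    Round-trips losslessly through :func:`read_mtx_triplet`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.counts)
    try:
        scipy.io.mmwrite(directory / "matrix.mtx", coo, field="integer")
    except OSError as exc:  # pragma: no cover - depends on filesystem state
        raise OSError(f"failed writing {directory / 'matrix.mtx'}: {exc}") from exc
    matrix.genes[GENE_COLUMNS].to_csv(directory / "genes.tsv", sep="\t",
                                      header=False, index=False)
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.write("".join(b + "\n" for b in matrix.barcodes))
    pd.DataFrame(
        [{"sample_id": matrix.sample_id, "patient_id": matrix.patient_id,
          "clinical_group": matrix.clinical_group}]
    ).to_csv(directory / "samples.tsv", sep="\t", index=False)
    if matrix.cell_labels is not None:
        pd.DataFrame({"barcode": matrix.barcodes,
                      "cell_type": matrix.cell_labels.values}).to_csv(
            directory / "cell_labels.tsv", sep="\t", index=False)
    return directory


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the published values.

    QC thresholds are retention bounds: "fewer than 200" / "more than 6000"
    are exclusive removals, so cells sitting exactly on a bound are kept.
    """

    # QC
    min_genes: int = 200
    max_genes: int = 6000
    max_mito_frac: float = 0.15
    max_umis: int = 60000
    gene_min_cells: int = 5
    # normalization / variable genes
    scale_factor: float = 10000.0
    n_variable_genes: int = 2000
    # CNV inference and malignant calling
    cnv_window: int = 101
    cnv_clip: float = 3.0
    cnv_top_frac: float = 0.05
    cnv_r_threshold: float = 0.3
    # NMF meta-programs
    nmf_k_min: int = 6
    nmf_k_max: int = 9
    nmf_top_n: int = 50
    nmf_robust_overlap: int = 35
    nmf_core_frac: float = 0.25
    nmf_min_cells: int = 20
    # signature scoring
    sig_n_bins: int = 25
    sig_n_background: int = 100
    # communication
    n_permutations: int = 999
    lr_hill_constant: float = 0.5
    lr_min_cells: int = 10
    # fallback clustering
    n_pcs: int = 30
    n_clusters: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.min_genes, self.max_genes, self.max_umis, self.gene_min_cells + 1,
               self.cnv_window, self.nmf_top_n) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.cnv_top_frac < 1:
            raise ValueError("cnv_top_frac must lie in (0, 1)")
        if self.nmf_robust_overlap > self.nmf_top_n:
            raise ValueError("robust_overlap cannot exceed top_n")
        if self.cnv_window % 2 == 0 or self.cnv_window < 3:
            raise ValueError("cnv_window must be odd and >= 3")

    @property
    def k_range(self) -> range:
        return range(self.nmf_k_min, self.nmf_k_max + 1)

    @classmethod
    def from_yaml(cls, path: os.PathLike | str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: os.PathLike | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
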