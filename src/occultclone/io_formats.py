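"""Readers and writers for every external format the pipeline touches.

The scCNV side speaks the 10x dialects: ``node_cnv_calls.bed`` (per-entity
copy-number segments, where entities are leaf cells followed by internal
phylogeny nodes), ``mappable_regions.bed`` (BED3), and
``per_cell_summary_metrics.csv`` (per-cell QC with a noisy flag and mean
ploidy). The scRNA side uses MatrixMarket triplet matrices with barcode /
feature sidecars. Gene annotation is accepted as GTF (1-based inclusive,
converted on read) or a plain TSV already in BED convention; gene sets come
as GMT.

All genomic intervals in memory are 0-based half-open and chromosome names
are normalized to the ``chr`` prefix, so synthetic and real data flow
through identical code paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .genome import normalize_chrom

SEGMENT_COLUMNS = ["chrom", "start", "end", "cell_id", "cn", "confidence"]


class ParseError(ValueError):
    """Malformed record in an input file; message names the file and line."""


@dataclass
class CountMatrix:
    """Sparse nonnegative-integer gene x cell counts with sidecar identifiers."""

    matrix: sp.csr_matrix  # genes x cells
    gene_ids: np.ndarray
    barcodes: np.ndarray
    gene_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.matrix.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.gene_ids)} genes / {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total UMI per cell (N_n)."""
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def subset_genes(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        return CountMatrix(
            self.matrix[idx, :],
            self.gene_ids[idx],
            self.barcodes,
            None if self.gene_names is None else np.asarray(self.gene_names, object)[idx],
        )

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        return CountMatrix(
            self.matrix[:, idx], self.gene_ids, self.barcodes[idx], self.gene_names
        )


def read_segment_calls(path, n_cells: int) -> pd.DataFrame:
    """Read a ``node_cnv_calls.bed``-dialect file into a segment-call table.

    Only leaf-cell rows (``entity_id < n_cells``) are kept; the internal
    phylogeny nodes the 10x pipeline appends after the leaves are dropped.
    Rows on chromosomes outside chr1-22/X/Y are rejected with a single
    summary warning. The result is sorted by (cell_id, chrom, start).
    """
    rows = []
    n_unknown = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(f"{path}:{lineno}: expected >=5 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
                entity = int(parts[3])
                cn = int(parts[4])
                conf = float(parts[5]) if len(parts) > 5 else np.nan
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            try:
                chrom = normalize_chrom(parts[0])
            except ValueError:
                n_unknown += 1
                continue
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start must be < end")
            if cn < 0:
                raise ParseError(f"{path}:{lineno}: copy number must be >= 0")
            if entity < n_cells:
                rows.append((chrom, start, end, entity, cn, conf))
    if n_unknown:
        warnings.warn(f"{path}: rejected {n_unknown} records on unknown chromosomes")
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return seg.sort_values(["cell_id", "chrom", "start"], kind="stable").reset_index(
        drop=True
    )


def write_segment_calls(seg: pd.DataFrame, path) -> None:
    out = seg[SEGMENT_COLUMNS].copy()
    out["confidence"] = out["confidence"].fillna(0.0)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_mappable_regions(path) -> pd.DataFrame:
    """Read a BED3 file of mappable regions; sorted, chr-normalized."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            try:
                chrom = normalize_chrom(parts[0])
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start must be < end")
            rows.append((chrom, start, end))
    reg = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    reg = reg.sort_values(["chrom", "start"]).reset_index(drop=True)
    # mappable regions must not overlap within a chromosome
    same = reg.chrom.values[1:] == reg.chrom.values[:-1]
    if np.any(same & (reg.start.values[1:] < reg.end.values[:-1])):
        raise ParseError(f"{path}: overlapping mappable regions")
    return reg


def write_mappable_regions(regions: pd.DataFrame, path) -> None:
    regions[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_cell_qc(path) -> pd.DataFrame:
    """Read per-cell QC metrics (barcode, cell_id, mean_ploidy, is_noisy)."""
    qc = pd.read_csv(path)
    required = {"barcode", "cell_id", "mean_ploidy", "is_noisy"}
    missing = required - set(qc.columns)
    if missing:
        raise ParseError(f"{path}: missing QC columns {sorted(missing)}")
    qc = qc[["barcode", "cell_id", "mean_ploidy", "is_noisy"]].copy()
    qc["cell_id"] = qc["cell_id"].astype(int)
    qc["is_noisy"] = qc["is_noisy"].astype(int).astype(bool)
    if qc["cell_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate cell_id")
    if (qc["mean_ploidy"] <= 0).any():
        raise ParseError(f"{path}: mean_ploidy must be positive")
    return qc


def write_cell_qc(qc: pd.DataFrame, path) -> None:
    out = qc[["barcode", "cell_id", "mean_ploidy", "is_noisy"]].copy()
    out["is_noisy"] = out["is_noisy"].astype(int)
    out.to_csv(path, index=False)


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene loci from GTF or TSV into 0-based half-open coordinates.

    GTF input (detected by extension ``.gtf``) keeps only ``gene`` features
    and converts 1-based inclusive coordinates. TSV input must already carry
    columns gene_id, gene_name, chrom, start, end, strand in BED convention.
    """
    path = Path(path)
    if path.suffix.lower() == ".gtf":
        return _read_gtf_genes(path)
    genes = pd.read_csv(path, sep="\t")
    required = {"gene_id", "gene_name", "chrom", "start", "end", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    genes = genes[["gene_id", "gene_name", "chrom", "start", "end", "strand"]].copy()
    genes["chrom"] = genes["chrom"].map(normalize_chrom)
    if (genes["start"] >= genes["end"]).any():
        raise ParseError(f"{path}: gene with start >= end")
    return genes.reset_index(drop=True)


def _read_gtf_genes(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if parts[2] != "gene":
                continue
            attrs = {}
            for item in parts[8].strip().strip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            try:
                chrom = normalize_chrom(parts[0])
            except ValueError:
                continue
            rows.append(
                (
                    attrs.get("gene_id", f"line{lineno}"),
                    attrs.get("gene_name", attrs.get("gene_id", f"line{lineno}")),
                    chrom,
                    int(parts[3]) - 1,  # GTF is 1-based inclusive
                    int(parts[4]),
                    parts[6],
                )
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "gene_name", "chrom", "start", "end", "strand"]
    )


def read_counts_mtx(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a MatrixMarket triplet matrix with feature/barcode sidecars.

    Duplicate triplets are summed. Sidecar row counts must match the matrix
    header dimensions. Features files may carry one column (gene id) or two
    or more (id, name, ...).
    """
    mat = scipy.io.mmread(matrix_path)
    feats = pd.read_csv(features_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].to_numpy(object)
    if mat.shape[0] != len(feats):
        raise ParseError(
            f"{matrix_path}: {mat.shape[0]} genes in matrix but "
            f"{len(feats)} rows in {features_path}"
        )
    if mat.shape[1] != len(barcodes):
        raise ParseError(
            f"{matrix_path}: {mat.shape[1]} cells in matrix but "
            f"{len(barcodes)} rows in {barcodes_path}"
        )
    gene_ids = feats[0].to_numpy(object)
    gene_names = feats[1].to_numpy(object) if feats.shape[1] > 1 else None
    return CountMatrix(mat.tocsr().astype(np.int64), gene_ids, barcodes, gene_names)


def write_counts_mtx(counts: CountMatrix, matrix_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(matrix_path), counts.matrix.tocoo(), field="integer")
    names = counts.gene_names if counts.gene_names is not None else counts.gene_ids
    pd.DataFrame({0: counts.gene_ids, 1: names}).to_csv(
        features_path, sep="\t", header=False, index=False
    )
    pd.Series(counts.barcodes).to_csv(barcodes_path, sep="\t", header=False, index=False)


def read_gene_sets_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping set-name -> gene list."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not [g for g in parts[2:] if g]:
                raise ParseError(f"{path}:{lineno}: empty gene set {parts[0]!r}")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gene_sets_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")
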