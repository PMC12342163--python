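"""Readers, writers and preprocessing for expression matrices and gene annotation.

The preprocessing contract: drop genes with total expression below a
threshold, drop rare reference classes, zero-fill the query onto the
reference gene axis, then log-normalize per cell and z-score per gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from gprint._chrom import chromosome_sort_key

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


def _check_unique(ids, what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class GeneCoordinateTable:
    """Gene → (chromosome, termination site) map defining the print order."""

    gene_ids: list[str]
    chromosomes: list[str]
    end_positions: np.ndarray

    def __post_init__(self) -> None:
        self.end_positions = np.asarray(self.end_positions, dtype=np.int64)
        if not (len(self.gene_ids) == len(self.chromosomes) == len(self.end_positions)):
            raise ValueError("gene_ids, chromosomes and end_positions must be parallel")
        _check_unique(self.gene_ids, "gene")
        if len(self.end_positions) and self.end_positions.min() < 1:
            raise ValueError("end positions must be >= 1")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def lookup(self) -> dict[str, tuple[str, int]]:
        return {
            g: (c, int(e))
            for g, c, e in zip(self.gene_ids, self.chromosomes, self.end_positions)
        }


@dataclass
class CountMatrix:
    """Raw nonnegative counts, cells x genes."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("counts must be nonnegative")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass
class LabelTable:
    """Per-cell label assignment (cell types, subtypes or group ids)."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.labels):
            raise ValueError("cell_ids and labels must be parallel")
        _check_unique(self.cell_ids, "cell")
        if any(not str(l) for l in self.labels):
            raise ValueError("labels must be non-empty strings")
        self.labels = [str(l) for l in self.labels]

    def __len__(self) -> int:
        return len(self.cell_ids)

    def to_dict(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.labels))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for l in self.labels:
            counts[l] = counts.get(l, 0) + 1
        return counts

    def subset(self, cell_ids: list[str]) -> "LabelTable":
        mapping = self.to_dict()
        missing = [c for c in cell_ids if c not in mapping]
        if missing:
            raise KeyError(f"cells without labels: {missing[:5]}")
        return LabelTable(list(cell_ids), [mapping[c] for c in cell_ids])


@dataclass
class NormalizedMatrix:
    """Log-normalized, per-gene standardized expression with its parameters."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    normalization_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("matrix shape does not match identifier lists")


# ---------------------------------------------------------------------------
# readers


def _read_expression_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: expression table has no data rows/columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row identifier {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate column identifier {dup!r}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            row = df.index[converted.isna().argmax()]
            raise FormatError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = converted
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in expression table")
    return df


def _find_mtx_component(d: Path, names: list[str], what: str) -> Path:
    for n in names:
        p = d / n
        if p.exists():
            return p
    raise FormatError(f"{d}: missing {what} file (looked for {names})")


def _read_expression_mtx(path: Path) -> pd.DataFrame:
    d = Path(path)
    if not d.is_dir():
        raise FormatError(f"{d}: MTX input must be a directory")
    mtx = _find_mtx_component(d, ["matrix.mtx"], "matrix")
    feat = _find_mtx_component(d, ["features.tsv", "genes.tsv"], "features")
    bc = _find_mtx_component(d, ["barcodes.tsv"], "barcodes")
    try:
        m = scipy.io.mmread(mtx)
    except ValueError as exc:
        raise FormatError(f"{mtx}: unreadable MatrixMarket file: {exc}") from exc
    genes = pd.read_csv(feat, sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(bc, sep="\t", header=None)[0].astype(str).tolist()
    dense = np.asarray(m.todense() if scipy.sparse.issparse(m) else m, dtype=np.float64)
    if dense.shape != (len(genes), len(cells)):
        raise FormatError(
            f"{mtx}: matrix is {dense.shape} but features/barcodes give "
            f"({len(genes)}, {len(cells)})"
        )
    return pd.DataFrame(dense, index=genes, columns=cells)


def read_expression(
    path: str | Path,
    format: str | None = None,
    orientation: str = "genes_by_cells",
) -> CountMatrix:
    """Read an expression matrix from CSV or a 10x-style MTX directory.

    CSV: header row and first column are identifiers. MTX: a directory with
    ``matrix.mtx`` plus ``features.tsv``/``genes.tsv`` and ``barcodes.tsv``,
    always genes x cells. The returned matrix is cells x genes regardless of
    the input orientation; ``orientation`` describes the CSV layout and is
    never auto-detected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.is_dir() else "csv"
    if format == "csv":
        df = _read_expression_csv(path)
        if orientation == "genes_by_cells":
            df = df.T
        elif orientation != "cells_by_genes":
            raise ValueError(f"unknown orientation {orientation!r}")
    elif format == "mtx":
        df = _read_expression_mtx(path).T  # MTX is always genes x cells
    else:
        raise ValueError(f"unknown format {format!r}")
    return CountMatrix(
        values=df.to_numpy(dtype=np.float64),
        cell_ids=[str(c) for c in df.index],
        gene_ids=[str(g) for g in df.columns],
    )


def read_labels(path: str | Path) -> LabelTable:
    """Read a labels CSV with columns ``cell_id,label`` (header optional)."""
    df = pd.read_csv(path, header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: labels CSV needs two columns (cell_id,label)")
    first = df.iloc[0]
    if str(first[0]).lower() in {"cell_id", "cell", "barcode"}:
        df = df.iloc[1:]
    return LabelTable(df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1].astype(str).tolist())


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            key, _, val = chunk.partition(" ")
            out[key] = val.strip().strip('"')
    return out


def _dedup_annotation(
    records: list[tuple[str, str, int]], source: str
) -> tuple[list[str], list[str], list[int]]:
    # keep, per gene, the occurrence smallest under the canonical genome order
    best: dict[str, tuple[tuple, str, int]] = {}
    order: list[str] = []
    n_dups = 0
    for gene, chrom, end in records:
        key = (chromosome_sort_key(chrom), end)
        if gene not in best:
            best[gene] = (key, chrom, end)
            order.append(gene)
        else:
            n_dups += 1
            if key < best[gene][0]:
                best[gene] = (key, chrom, end)
    if n_dups:
        warnings.warn(
            f"{source}: {n_dups} duplicate gene record(s) dropped "
            "(kept the smallest (chromosome, end) per gene)",
            stacklevel=3,
        )
    chroms = [best[g][1] for g in order]
    ends = [best[g][2] for g in order]
    return order, chroms, ends


def read_gene_annotation(path: str | Path, format: str | None = None) -> GeneCoordinateTable:
    """Read gene coordinates from a GTF file or a ``gene_id<TAB>chrom<TAB>end`` TSV.

    GTF coordinates are 1-based inclusive; the end of the gene-level feature
    is taken as the termination site. Duplicate gene ids keep the first
    occurrence under the canonical (chromosome, end) order, with a warning.
    """
    path = Path(path)
    if format is None:
        format = "gtf" if path.suffix.lower() in {".gtf", ".gff"} else "tsv"
    records: list[tuple[str, str, int]] = []
    if format == "gtf":
        gene_rows: list[tuple[str, str, int]] = []
        other_rows: list[tuple[str, str, int]] = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 9:
                    raise FormatError(f"{path}:{ln}: expected 9 tab-separated fields")
                chrom, _source, feature, _start, end, _score, _strand, _frame, attrs = fields
                try:
                    end_pos = int(end)
                except ValueError as exc:
                    raise FormatError(f"{path}:{ln}: unparseable end coordinate {end!r}") from exc
                a = _parse_gtf_attributes(attrs)
                gene = a.get("gene_id") or a.get("gene_name")
                if gene is None:
                    continue
                (gene_rows if feature == "gene" else other_rows).append((gene, chrom, end_pos))
        if gene_rows:
            records = gene_rows
        elif other_rows:
            warnings.warn(f"{path}: no gene-level records; using per-gene maximum feature end")
            agg: dict[str, tuple[str, int]] = {}
            for gene, chrom, end_pos in other_rows:
                if gene not in agg or end_pos > agg[gene][1]:
                    agg[gene] = (chrom, end_pos)
            records = [(g, c, e) for g, (c, e) in agg.items()]
        else:
            raise FormatError(f"{path}: no gene records found")
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 3:
            raise FormatError(f"{path}: annotation TSV needs columns gene_id, chromosome, end")
        if str(df.iloc[0, 0]).lower() in {"gene_id", "gene"}:
            df = df.iloc[1:]
        if df.empty:
            raise FormatError(f"{path}: no gene records found")
        for _, row in df.iterrows():
            try:
                end_pos = int(float(row[2]))
            except ValueError as exc:
                raise FormatError(f"{path}: unparseable end coordinate {row[2]!r}") from exc
            records.append((str(row[0]), str(row[1]), end_pos))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    genes, chroms, ends = _dedup_annotation(records, str(path))
    return GeneCoordinateTable(genes, chroms, np.asarray(ends))


# ---------------------------------------------------------------------------
# preprocessing


def filter_low_expression_genes(
    m: CountMatrix, min_total: float = 2
) -> tuple[CountMatrix, list[str]]:
    """Keep genes whose total count over all cells is >= ``min_total``.

    Returns the filtered matrix and the list of removed gene ids.
    """
    totals = m.values.sum(axis=0)
    keep = totals >= min_total
    removed = [g for g, k in zip(m.gene_ids, keep) if not k]
    if not keep.any():
        warnings.warn("all genes fall below the expression threshold")
    out = CountMatrix(m.values[:, keep], list(m.cell_ids), [g for g, k in zip(m.gene_ids, keep) if k])
    return out, removed


def filter_rare_classes(
    m: CountMatrix, labels: LabelTable, min_cells: int = 10
) -> tuple[CountMatrix, LabelTable, list[str]]:
    """Remove all cells of any class with fewer than ``min_cells`` members.

    Reference-set preprocessing only; query data must never pass through
    this. A class with exactly ``min_cells`` members is kept.
    """
    lab = labels.subset(m.cell_ids)
    counts = lab.class_counts()
    removed_classes = sorted(l for l, n in counts.items() if n < min_cells)
    if len(removed_classes) == len(counts):
        raise ValueError(
            f"every class has fewer than {min_cells} cells; nothing left to train on"
        )
    keep = [l not in removed_classes for l in lab.labels]
    kept_cells = [c for c, k in zip(m.cell_ids, keep) if k]
    out_m = CountMatrix(m.values[np.asarray(keep)], kept_cells, list(m.gene_ids))
    out_l = LabelTable(kept_cells, [l for l, k in zip(lab.labels, keep) if k])
    if removed_classes:
        logger.info("removed rare classes: %s", removed_classes)
    return out_m, out_l, removed_classes


def align_gene_space(
    query: CountMatrix, reference_genes: list[str]
) -> tuple[CountMatrix, list[str]]:
    """Project the query onto the reference gene axis.

    Genes missing from the query become zero columns; query-only genes are
    dropped and returned. Shared values are copied bit-exactly.
    """
    if not reference_genes:
        raise ValueError("reference gene list is empty")
    idx = {g: j for j, g in enumerate(query.gene_ids)}
    shared = [g for g in reference_genes if g in idx]
    if not shared:
        raise ValueError("no overlap between query genes and reference genes")
    out = np.zeros((query.n_cells, len(reference_genes)), dtype=np.float64)
    for j, g in enumerate(reference_genes):
        if g in idx:
            out[:, j] = query.values[:, idx[g]]
    dropped = [g for g in query.gene_ids if g not in set(reference_genes)]
    if dropped:
        logger.info("dropped %d query-only genes", len(dropped))
    return CountMatrix(out, list(query.cell_ids), list(reference_genes)), dropped


def normalize_and_scale(
    m: CountMatrix,
    scale_factor: float = 1e4,
    clip: float = 10.0,
    reference_record: dict | None = None,
) -> NormalizedMatrix:
    """Log-normalize per cell, then z-score per gene with clipping.

    Step 1, per cell: ``x' = ln(1 + x * scale_factor / cell_total)``.
    Step 2, per gene: ``z = (x' - mean) / sd`` (sample sd, ddof=1), constant
    genes set to 0, clipped to ``[-clip, clip]``. Pass ``reference_record``
    (a previous ``normalization_record``) to standardize with the reference's
    per-gene statistics instead of this matrix's own.
    """
    totals = m.values.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(f"cell with zero total count: {m.cell_ids[zero[0]]!r}")
    lognorm = np.log1p(m.values * (scale_factor / totals[:, None]))
    if reference_record is not None:
        ref_genes = list(reference_record["gene_ids"])
        if ref_genes != list(m.gene_ids):
            raise ValueError("reference_record gene axis does not match this matrix")
        means = np.asarray(reference_record["gene_means"], dtype=np.float64)
        sds = np.asarray(reference_record["gene_sds"], dtype=np.float64)
        scale_factor = float(reference_record["scale_factor"])
        clip = float(reference_record["clip"])
    else:
        means = lognorm.mean(axis=0)
        if m.n_cells > 1:
            sds = lognorm.std(axis=0, ddof=1)
        else:
            sds = np.zeros(m.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (lognorm - means) / sds
    z[:, sds == 0] = 0.0
    z = np.clip(z, -clip, clip)
    record = {
        "scale_factor": float(scale_factor),
        "clip": float(clip),
        "gene_ids": list(m.gene_ids),
        "gene_means": means,
        "gene_sds": sds,
    }
    return NormalizedMatrix(z, list(m.cell_ids), list(m.gene_ids), record)
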