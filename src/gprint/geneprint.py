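"""Construction of genome-ordered per-cell signals ("gene prints").

A gene print is nothing more than a cell's normalized expression values
rearranged into genome coordinate order — chromosome rank first, then gene
termination site — so that a 1D convolution sees genomically adjacent genes
in adjacent positions. The "feature print" restricts the axis to the union
of marker genes for the candidate labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gprint._chrom import chromosome_sort_key
from gprint.io_prep import GeneCoordinateTable, LabelTable, NormalizedMatrix

logger = logging.getLogger(__name__)


@dataclass
class OrderedGeneList:
    """Genes sorted by (canonical chromosome rank, termination site, gene id)."""

    genes: list[str]
    keys: list[tuple[tuple[int, str], int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.keys and len(self.keys) != len(self.genes):
            raise ValueError("keys must parallel genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ordered gene list contains duplicates")
        if self.keys:
            for a, b in zip(self.keys, self.keys[1:]):
                if b < a:
                    raise ValueError("ordered gene keys are not non-decreasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PrintMatrix:
    """Per-cell 1D signals on an ordered gene axis."""

    signals: np.ndarray
    cell_ids: list[str]
    ordered_genes: OrderedGeneList

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.shape != (len(self.cell_ids), len(self.ordered_genes)):
            raise ValueError(
                f"signals shape {self.signals.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.ordered_genes)} genes"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.signals, index=self.cell_ids, columns=self.ordered_genes.genes)


@dataclass
class MarkerSet:
    """Marker genes per candidate label."""

    by_label: dict[str, list[str]]

    def __post_init__(self) -> None:
        for label, genes in self.by_label.items():
            if not genes:
                raise ValueError(f"label {label!r} has an empty marker list")

    def union(self) -> list[str]:
        seen: set[str] = set()
        out: list[str] = []
        for genes in self.by_label.values():
            for g in genes:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out


def read_markers(path) -> MarkerSet:
    """Read a marker CSV with columns ``label,gene_id`` (one row per marker)."""
    df = pd.read_csv(path, header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: marker CSV needs two columns (label,gene_id)")
    if str(df.iloc[0, 0]).lower() in {"label", "cell_type", "celltype"}:
        df = df.iloc[1:]
    by_label: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        by_label.setdefault(str(row.iloc[0]), []).append(str(row.iloc[1]))
    return MarkerSet(by_label)


def order_genes(
    genes: list[str], ann: GeneCoordinateTable
) -> tuple[OrderedGeneList, list[str]]:
    """Sort ``genes`` by (chromosome rank, termination site, gene id).

    Genes absent from the annotation cannot be placed on the print and are
    returned separately as dropped.
    """
    if len(ann) == 0:
        raise ValueError("annotation is empty")
    lut = ann.lookup()
    found = [g for g in genes if g in lut]
    dropped = [g for g in genes if g not in lut]
    if not found:
        raise ValueError("none of the input genes are present in the annotation")
    if dropped:
        logger.info("dropped %d genes absent from the annotation", len(dropped))
    decorated = sorted(
        found, key=lambda g: (chromosome_sort_key(lut[g][0]), lut[g][1], g)
    )
    keys = [(chromosome_sort_key(lut[g][0]), lut[g][1]) for g in decorated]
    return OrderedGeneList(decorated, keys), dropped


def build_gene_prints(m: NormalizedMatrix, order: OrderedGeneList) -> PrintMatrix:
    """Rearrange normalized values into genome order; pure column permutation."""
    idx = {g: j for j, g in enumerate(m.gene_ids)}
    missing = [g for g in order.genes if g not in idx]
    if missing:
        raise ValueError(
            f"genes in the print order are missing from the matrix "
            f"(run align_gene_space first): {missing[:5]}"
        )
    cols = np.asarray([idx[g] for g in order.genes], dtype=np.intp)
    return PrintMatrix(m.values[:, cols], list(m.cell_ids), order)


def build_feature_prints(
    m: NormalizedMatrix, markers: MarkerSet, order: OrderedGeneList
) -> tuple[PrintMatrix, list[str]]:
    """Restrict the ordered axis to the union of all labels' marker genes.

    Markers present in the order but absent from the matrix are zero-filled;
    markers with no genome position are dropped. Both groups are reported in
    the returned missing list.
    """
    marker_union = set(markers.union())
    axis = [g for g in order.genes if g in marker_union]
    unplaced = [g for g in markers.union() if g not in set(order.genes)]
    if not axis:
        raise ValueError("no marker gene has a position on the ordered axis")
    idx = {g: j for j, g in enumerate(m.gene_ids)}
    if not any(g in idx for g in axis):
        raise ValueError("no marker gene is present in the expression matrix")
    signals = np.zeros((len(m.cell_ids), len(axis)), dtype=np.float64)
    zero_filled: list[str] = []
    for j, g in enumerate(axis):
        if g in idx:
            signals[:, j] = m.values[:, idx[g]]
        else:
            zero_filled.append(g)
    keys = []
    if order.keys:
        key_by_gene = dict(zip(order.genes, order.keys))
        keys = [key_by_gene[g] for g in axis]
    missing = zero_filled + unplaced
    if missing:
        logger.info("feature print: %d marker genes zero-filled or unplaced", len(missing))
    return PrintMatrix(signals, list(m.cell_ids), OrderedGeneList(axis, keys)), missing


def aggregate_prints_by_group(
    p: PrintMatrix, groups: LabelTable, how: str = "mean"
) -> PrintMatrix:
    """Collapse prints to one row per group (arithmetic mean, or median)."""
    if how not in {"mean", "median"}:
        raise ValueError(f"unknown aggregation {how!r}")
    assignment = groups.to_dict()
    missing = [c for c in p.cell_ids if c not in assignment]
    if missing:
        raise ValueError(f"cells without group assignment: {missing[:5]}")
    members: dict[str, list[int]] = {}
    for i, c in enumerate(p.cell_ids):
        members.setdefault(assignment[c], []).append(i)
    for g in set(assignment.values()) - set(members):
        warnings.warn(f"group {g!r} has no member cells; skipped")
    group_ids = sorted(members)
    agg = np.empty((len(group_ids), p.signals.shape[1]), dtype=np.float64)
    for r, g in enumerate(group_ids):
        block = p.signals[members[g]]
        agg[r] = block.mean(axis=0) if how == "mean" else np.median(block, axis=0)
    return PrintMatrix(agg, group_ids, p.ordered_genes)
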