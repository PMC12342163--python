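"""Synthetic genome-annotated scRNA-seq generator.

Produces labeled reference/query count matrices whose cell types differ by
contiguous genomic blocks of over-expressed signature genes — the positional
co-expression structure the gene-print classifier is designed to exploit —
with negative-binomial counts, per-cell library-size variation, dropout and
per-gene multiplicative batch effects on the query side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from gprint.io_prep import CountMatrix, GeneCoordinateTable, LabelTable


@dataclass
class SimSpec:
    n_genes: int = 2000
    n_chromosomes: int = 10
    n_cell_types: int = 5
    cells_per_type: int | tuple[int, ...] = 200
    signature_block_length: int = 40
    signature_fold_change: float = 6.0
    baseline_mean: float = 0.5
    gene_mean_sd: float = 0.6  # log-normal spread of gene-wise baseline means
    dispersion: float = 2.0  # negative-binomial size parameter
    dropout_rate: float = 0.3
    library_size_spread: float = 0.3
    batch_effect_sd: float = 0.3
    gene_drop_fraction: float = 0.0  # query genes removed to exercise zero-fill
    scatter_signatures: bool = False  # place signature genes randomly, not in blocks
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cells_per_type, (list, tuple)):
            self.cells_per_type = tuple(int(n) for n in self.cells_per_type)
            if len(self.cells_per_type) != self.n_cell_types:
                raise ValueError("cells_per_type length must equal n_cell_types")
        if self.n_genes < 1 or self.n_chromosomes < 1 or self.n_cell_types < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.signature_block_length < 1:
            raise ValueError("signature_block_length must be positive")

    def counts_per_type(self) -> tuple[int, ...]:
        if isinstance(self.cells_per_type, tuple):
            return self.cells_per_type
        return (int(self.cells_per_type),) * self.n_cell_types

    def type_names(self) -> list[str]:
        return [f"type{t}" for t in range(self.n_cell_types)]


@dataclass
class SimTruth:
    annotation: GeneCoordinateTable
    block_map: dict[str, np.ndarray]  # type -> gene indices of its signature
    labels: LabelTable
    gene_means: np.ndarray = field(default_factory=lambda: np.asarray([]))
    batch_factors: np.ndarray | None = None


def generate_annotation(spec: SimSpec) -> GeneCoordinateTable:
    """Synthetic genes in contiguous chromosome runs with strictly increasing
    termination sites; deterministic by seed."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes))
    genes = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    per_chrom = np.full(spec.n_chromosomes, spec.n_genes // spec.n_chromosomes)
    per_chrom[: spec.n_genes % spec.n_chromosomes] += 1
    chroms: list[str] = []
    ends: list[int] = []
    for c, n in enumerate(per_chrom, start=1):
        gaps = rng.integers(1, 10_000, size=int(n))
        positions = np.cumsum(gaps)
        chroms.extend([f"chr{c}"] * int(n))
        ends.extend(int(p) for p in positions)
    return GeneCoordinateTable(genes, chroms, np.asarray(ends))


def _signature_indices(spec: SimSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    segment = spec.n_genes // spec.n_cell_types
    if spec.signature_block_length > segment:
        raise ValueError(
            f"signature blocks of length {spec.signature_block_length} over "
            f"{spec.n_cell_types} types would overlap within {spec.n_genes} genes"
        )
    out: dict[str, np.ndarray] = {}
    if spec.scatter_signatures:
        perm = rng.permutation(spec.n_genes)
        for t, name in enumerate(spec.type_names()):
            lo = t * spec.signature_block_length
            out[name] = np.sort(perm[lo : lo + spec.signature_block_length])
    else:
        for t, name in enumerate(spec.type_names()):
            start = t * segment
            out[name] = np.arange(start, start + spec.signature_block_length)
    return out


def _nb_counts(
    mean: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson mixture: mean mu, variance mu + mu^2 / dispersion."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam).astype(np.float64)


def _draw_cells(
    spec: SimSpec,
    gene_means: np.ndarray,
    block_map: dict[str, np.ndarray],
    cell_prefix: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str], list[str]]:
    counts_per_type = spec.counts_per_type()
    n_cells = sum(counts_per_type)
    values = np.empty((n_cells, spec.n_genes))
    cell_ids: list[str] = []
    labels: list[str] = []
    width = len(str(n_cells))
    row = 0
    for name, n in zip(spec.type_names(), counts_per_type):
        mu_type = gene_means.copy()
        mu_type[block_map[name]] *= spec.signature_fold_change
        for _ in range(n):
            lib = rng.lognormal(0.0, spec.library_size_spread)
            x = _nb_counts(mu_type * lib, spec.dispersion, rng)
            if spec.dropout_rate > 0:
                x *= rng.random(spec.n_genes) >= spec.dropout_rate
            values[row] = x
            cell_ids.append(f"{cell_prefix}{row:0{width}d}")
            labels.append(name)
            row += 1
    return values, cell_ids, labels


def generate_reference(spec: SimSpec) -> tuple[CountMatrix, SimTruth]:
    """Labeled reference counts plus the ground truth used to score queries."""
    annotation = generate_annotation(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    gene_means = rng.lognormal(np.log(spec.baseline_mean), spec.gene_mean_sd, spec.n_genes)
    block_map = _signature_indices(spec, rng)
    values, cell_ids, labels = _draw_cells(spec, gene_means, block_map, "refcell", rng)
    # guard against all-zero cells (possible at extreme dropout): bump one count
    zero = values.sum(axis=1) == 0
    values[zero, 0] = 1.0
    matrix = CountMatrix(values, cell_ids, list(annotation.gene_ids))
    truth = SimTruth(annotation, block_map, LabelTable(cell_ids, labels), gene_means)
    return matrix, truth


def generate_query(
    spec: SimSpec, truth: SimTruth
) -> tuple[CountMatrix, LabelTable]:
    """New cells from the same type models, distorted by per-gene batch
    factors and fresh dropout; optionally drops genes to exercise zero-fill."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    batch = rng.lognormal(0.0, spec.batch_effect_sd, spec.n_genes)
    truth.batch_factors = batch
    values, cell_ids, labels = _draw_cells(
        spec, truth.gene_means * batch, truth.block_map, "qcell", rng
    )
    zero = values.sum(axis=1) == 0
    values[zero, 0] = 1.0
    gene_ids = list(truth.annotation.gene_ids)
    if spec.gene_drop_fraction > 0:
        n_drop = int(np.ceil(spec.gene_drop_fraction * spec.n_genes))
        drop = set(rng.choice(spec.n_genes, size=n_drop, replace=False).tolist())
        keep = [j for j in range(spec.n_genes) if j not in drop]
        values = values[:, keep]
        gene_ids = [gene_ids[j] for j in keep]
    return CountMatrix(values, cell_ids, gene_ids), LabelTable(cell_ids, labels)


def true_markers(truth: SimTruth) -> dict[str, list[str]]:
    """The signature genes per type, as a marker map for the group variant."""
    genes = truth.annotation.gene_ids
    return {t: [genes[j] for j in idx] for t, idx in truth.block_map.items()}


# ---------------------------------------------------------------------------
# fixture writers (the same formats the readers consume)


def write_expression_csv(m: CountMatrix, path: str | Path) -> None:
    """Genes x cells CSV, the reader's default orientation."""
    import pandas as pd

    pd.DataFrame(m.values.T, index=m.gene_ids, columns=m.cell_ids).to_csv(path)


def write_expression_mtx(m: CountMatrix, directory: str | Path) -> None:
    """10x-style triplet: matrix.mtx (genes x cells) + features + barcodes."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(m.values.T)
    scipy.io.mmwrite(d / "matrix.mtx", sparse)
    (d / "features.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
    (d / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))


def write_labels_csv(labels: LabelTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id,label\n")
        for c, l in zip(labels.cell_ids, labels.labels):
            fh.write(f"{c},{l}\n")


def write_annotation_tsv(ann: GeneCoordinateTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\tend\n")
        for g, c, e in zip(ann.gene_ids, ann.chromosomes, ann.end_positions):
            fh.write(f"{g}\t{c}\t{e}\n")


def write_annotation_gtf(ann: GeneCoordinateTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g, c, e in zip(ann.gene_ids, ann.chromosomes, ann.end_positions):
            start = max(1, int(e) - 500)
            fh.write(
                f"{c}\tsynthetic\tgene\t{start}\t{int(e)}\t.\t+\t.\t"
                f'gene_id "{g}"; gene_name "{g}";\n'
            )


def write_markers_csv(markers: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label,gene_id\n")
        for label in markers:
            for g in markers[label]:
                fh.write(f"{label},{g}\n")
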