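# gprint

Reference-based cell-type annotation for scRNA-seq built on genome-ordered
one-dimensional expression signals ("gene prints").

Each cell's normalized expression profile is rearranged into genome
coordinate order — genes sorted by chromosome, then by termination site — so
that genomically adjacent (and often co-regulated) genes occupy adjacent
positions of a 1D signal. A small convolutional network (two conv layers of
16 kernels, size 3 → max-pool → flatten → dense softmax) is trained on a
labeled reference and transfers labels to query cells. A marker-restricted
variant ("feature prints" + feed-forward network) supports group-level
annotation of pre-clustered data.

## Layout

| module | role |
|---|---|
| `gprint.io_prep` | CSV/MTX expression readers, GTF/TSV gene annotation, gene/class filtering, zero-fill gene-space alignment, log-normalization + per-gene scaling |
| `gprint.geneprint` | genome ordering, gene-print / feature-print construction, group aggregation |
| `gprint.classifiers` | the 1D-CNN and feed-forward networks (pure NumPy, seeded), prediction, model save/load |
| `gprint.evaluation` | stratified splits, k-fold CV, confusion matrices, precision/recall/F1/TPR/FPR/accuracy/AUC |
| `gprint.synthetic` | seeded generator of annotated, labeled reference/query datasets (NB counts, dropout, library-size and batch effects, contiguous signature blocks) |
| `gprint.cli` | `gprint simulate / train / annotate / evaluate` |

## CLI

Generate a synthetic fixture, train, and annotate:

```sh
gprint simulate --out fixture --seed 7
gprint train --ref fixture/ref.csv --ref-labels fixture/ref_labels.csv \
    --annotation fixture/annotation.tsv --out run --seed 0
gprint annotate --query fixture/query.csv --model run/model --out anno
```

or do everything in one step (train + annotate):

```sh
gprint annotate --ref fixture/ref.csv --ref-labels fixture/ref_labels.csv \
    --query fixture/query.csv --annotation fixture/annotation.tsv \
    --out anno --seed 0
```

`anno/anno_result.csv` holds one row per query cell: `cell_id`,
`predicted_label`, and one probability column per reference label.
`run_manifest.json` records all resolved parameters, seeds and input
checksums. Group-level annotation: add `--mode group --markers markers.csv`
(columns `label,gene_id`) and optionally `--query-groups clusters.csv` to
vote within clusters. `--model NAME --registry DIR` resolves saved models by
name.

Evaluation (70/30 split, then 5-fold CV on the test partition; use
`--whole-data` for conventional CV):

```sh
gprint evaluate --ref fixture/ref.csv --ref-labels fixture/ref_labels.csv \
    --annotation fixture/annotation.tsv --out eval --seed 0
```

writes `cv_result.csv`, `metrics_report.csv`, `confusion_matrix.csv`.

## Expression input formats

- CSV: header row and first column are identifiers; genes × cells by default
  (`--orientation cells_by_genes` to override — never auto-detected).
- MTX: a directory with `matrix.mtx`, `features.tsv`/`genes.tsv`,
  `barcodes.tsv`, genes × cells.
- Annotation: GTF (gene-level records, 1-based inclusive end) or a TSV with
  columns `gene_id`, `chromosome`, `end`.

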