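"""The two annotation networks: a 1D-CNN on full gene prints and a
feed-forward (back-propagation) network on marker-restricted feature prints.

The CNN is the six-layer layout: input, two convolutional layers (16 kernels
of size 3 each), one max-pooling layer, one flatten layer, and one dense
softmax output sized to the label vocabulary. Training is seeded and fully
deterministic on one machine.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gprint import _nn
from gprint.geneprint import OrderedGeneList, PrintMatrix
from gprint.io_prep import LabelTable

FORMAT_VERSION = 1


@dataclass
class CnnSpec:
    """Hyperparameters of the gene-print CNN.

    ``input_length`` and ``n_classes`` are filled in at training time from
    the reference data; everything else is overridable.
    """

    input_length: int | None = None
    n_classes: int | None = None
    conv_layers: int = 2
    kernels_per_layer: int = 16
    kernel_size: int = 3
    pool_size: int = 2
    dense_activation: str = "softmax"
    hidden_activation: str = "relu"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32
    validation_fraction: float = 0.1
    patience: int = 5
    seed: int = 0


@dataclass
class BpSpec:
    """Hyperparameters of the feature-print feed-forward network."""

    input_length: int | None = None
    n_classes: int | None = None
    hidden_layers: tuple[int, ...] = (128, 64)
    hidden_activation: str = "relu"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 32
    validation_fraction: float = 0.1
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(int(h) for h in self.hidden_layers)
        if not self.hidden_layers:
            raise ValueError("at least one hidden layer is required")


@dataclass
class TrainedClassifier:
    spec: CnnSpec | BpSpec
    network: _nn.Sequential
    label_vocabulary: list[str]
    ordered_genes: list[str]
    training_log: list[dict] = field(default_factory=list)

    @property
    def model_type(self) -> str:
        return "cnn" if isinstance(self.spec, CnnSpec) else "bp"

    def predict(self, query: PrintMatrix) -> "PredictionTable":
        return predict(self, query)


@dataclass
class PredictionTable:
    cell_ids: list[str]
    probabilities: np.ndarray
    label_vocabulary: list[str]
    predicted_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.shape != (len(self.cell_ids), len(self.label_vocabulary)):
            raise ValueError("probability matrix shape mismatch")
        if self.probabilities.size:
            if self.probabilities.min() < 0:
                raise ValueError("negative probability")
            sums = self.probabilities.sum(axis=1)
            if np.abs(sums - 1).max() > 1e-6:
                raise ValueError("probability rows must sum to 1 within 1e-6")
        if not self.predicted_labels:
            # np.argmax takes the first maximum, i.e. ties break by vocabulary order
            idx = self.probabilities.argmax(axis=1)
            self.predicted_labels = [self.label_vocabulary[i] for i in idx]

    def __len__(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cell_id": self.cell_ids, "predicted_label": self.predicted_labels})
        for j, label in enumerate(self.label_vocabulary):
            df[f"prob_{label}"] = self.probabilities[:, j]
        return df


def _build_cnn(spec: CnnSpec, rng: np.random.Generator) -> _nn.Sequential:
    assert spec.input_length is not None and spec.n_classes is not None
    layers: list[_nn.Layer] = []
    length = spec.input_length
    c_in = 1
    for _ in range(spec.conv_layers):
        layers.append(_nn.Conv1D(c_in, spec.kernels_per_layer, spec.kernel_size, rng))
        layers.append(_nn.ReLU())
        length = length - spec.kernel_size + 1
        c_in = spec.kernels_per_layer
    layers.append(_nn.MaxPool1D(spec.pool_size))
    length = length // spec.pool_size
    layers.append(_nn.Flatten())
    layers.append(_nn.Dense(length * c_in, spec.n_classes, rng))
    return _nn.Sequential(layers)


def _build_bp(spec: BpSpec, rng: np.random.Generator) -> _nn.Sequential:
    assert spec.input_length is not None and spec.n_classes is not None
    layers: list[_nn.Layer] = []
    n_in = spec.input_length
    for width in spec.hidden_layers:
        layers.append(_nn.Dense(n_in, width, rng))
        layers.append(_nn.ReLU())
        n_in = width
    layers.append(_nn.Dense(n_in, spec.n_classes, rng))
    return _nn.Sequential(layers)


def _prepare_training(
    ref: PrintMatrix, labels: LabelTable
) -> tuple[np.ndarray, list[str]]:
    lab = labels.subset(ref.cell_ids)
    vocab = sorted(set(lab.labels))
    if len(vocab) < 2:
        raise ValueError(f"training needs at least 2 classes, got {vocab}")
    index = {l: i for i, l in enumerate(vocab)}
    y = np.asarray([index[l] for l in lab.labels], dtype=np.intp)
    return y, vocab


def train_gprint(
    ref: PrintMatrix, labels: LabelTable, spec: CnnSpec | None = None
) -> TrainedClassifier:
    """Fit the gene-print CNN on a labeled reference."""
    spec = dataclasses.replace(spec) if spec is not None else CnnSpec()
    y, vocab = _prepare_training(ref, labels)
    spec.input_length = ref.signals.shape[1]
    spec.n_classes = len(vocab)
    rng = np.random.default_rng(spec.seed)
    net = _build_cnn(spec, rng)
    x = ref.signals[:, :, None]
    log = _nn.fit_network(
        net, x, y, len(vocab),
        epochs=spec.epochs, batch_size=spec.batch_size,
        optimizer=spec.optimizer, learning_rate=spec.learning_rate,
        validation_fraction=spec.validation_fraction, patience=spec.patience,
        rng=rng,
    )
    return TrainedClassifier(spec, net, vocab, list(ref.ordered_genes.genes), log)


def train_gprint_group(
    ref: PrintMatrix, labels: LabelTable, spec: BpSpec | None = None
) -> TrainedClassifier:
    """Fit the feed-forward network on marker-restricted feature prints."""
    spec = dataclasses.replace(spec) if spec is not None else BpSpec()
    y, vocab = _prepare_training(ref, labels)
    spec.input_length = ref.signals.shape[1]
    spec.n_classes = len(vocab)
    rng = np.random.default_rng(spec.seed)
    net = _build_bp(spec, rng)
    log = _nn.fit_network(
        net, ref.signals, y, len(vocab),
        epochs=spec.epochs, batch_size=spec.batch_size,
        optimizer=spec.optimizer, learning_rate=spec.learning_rate,
        validation_fraction=spec.validation_fraction, patience=spec.patience,
        rng=rng,
    )
    return TrainedClassifier(spec, net, vocab, list(ref.ordered_genes.genes), log)


def _check_gene_axis(model: TrainedClassifier, query: PrintMatrix) -> None:
    qgenes = query.ordered_genes.genes
    mgenes = model.ordered_genes
    if qgenes == mgenes:
        return
    n = min(len(qgenes), len(mgenes))
    for j in range(n):
        if qgenes[j] != mgenes[j]:
            raise ValueError(
                f"query gene axis diverges from the model's at position {j}: "
                f"{qgenes[j]!r} != {mgenes[j]!r}"
            )
    raise ValueError(
        f"query gene axis has {len(qgenes)} genes but the model expects {len(mgenes)}"
    )


def predict(
    model: TrainedClassifier,
    query: PrintMatrix,
    batch_size: int = 128,
    min_probability: float | None = None,
    unassigned_label: str = "Unassigned",
) -> PredictionTable:
    """Per-cell class probabilities and argmax labels for a query print matrix.

    Evaluation is chunked to keep the convolution's window buffers small.
    With ``min_probability`` set, cells whose top probability falls below it
    are labeled ``unassigned_label`` instead of the argmax (off by default;
    every cell normally receives a label).
    """
    _check_gene_axis(model, query)
    x = query.signals[:, :, None] if model.model_type == "cnn" else query.signals
    chunks = [
        _nn.softmax(model.network.forward(x[i : i + batch_size], train=False))
        for i in range(0, x.shape[0], batch_size)
    ]
    probs = np.concatenate(chunks, axis=0) if chunks else np.zeros((0, len(model.label_vocabulary)))
    labels: list[str] = []
    if min_probability is not None and len(probs):
        top = probs.max(axis=1)
        arg = probs.argmax(axis=1)
        labels = [
            model.label_vocabulary[a] if t >= min_probability else unassigned_label
            for a, t in zip(arg, top)
        ]
    return PredictionTable(list(query.cell_ids), probs, list(model.label_vocabulary), labels)


def predict_groups(
    model: TrainedClassifier,
    query: PrintMatrix,
    groups: LabelTable,
    mode: str = "vote",
) -> PredictionTable:
    """Group-level annotation: majority vote over per-cell predictions, or
    prediction on per-group mean prints. One output row per group."""
    from gprint.geneprint import aggregate_prints_by_group

    if mode == "mean_print":
        agg = aggregate_prints_by_group(query, groups)
        return predict(model, agg)
    if mode != "vote":
        raise ValueError(f"unknown mode {mode!r}")
    per_cell = predict(model, query)
    assignment = groups.to_dict()
    missing = [c for c in query.cell_ids if c not in assignment]
    if missing:
        raise ValueError(f"cells without group assignment: {missing[:5]}")
    members: dict[str, list[int]] = {}
    for i, c in enumerate(per_cell.cell_ids):
        members.setdefault(assignment[c], []).append(i)
    group_ids = sorted(members)
    vocab = per_cell.label_vocabulary
    probs = np.empty((len(group_ids), len(vocab)))
    winners: list[str] = []
    for r, g in enumerate(group_ids):
        idx = members[g]
        votes = np.zeros(len(vocab), dtype=np.intp)
        for i in idx:
            votes[vocab.index(per_cell.predicted_labels[i])] += 1
        winners.append(vocab[int(votes.argmax())])  # ties: first in vocabulary order
        probs[r] = per_cell.probabilities[idx].mean(axis=0)
    return PredictionTable(group_ids, probs, list(vocab), winners)


# ---------------------------------------------------------------------------
# persistence


def _content_checksum(spec_text: str, weights: list[np.ndarray], log_text: str) -> str:
    h = hashlib.sha256()
    h.update(spec_text.encode())
    for w in weights:
        h.update(str(w.shape).encode())
        h.update(np.ascontiguousarray(w, dtype=np.float64).tobytes())
    h.update(log_text.encode())
    return h.hexdigest()


def _log_to_csv(log: list[dict]) -> str:
    if not log:
        return "epoch\n"
    cols: list[str] = []
    for entry in log:
        for k in entry:
            if k not in cols:
                cols.append(k)
    df = pd.DataFrame(log, columns=cols)
    return df.to_csv(index=False)


def save_model(model: TrainedClassifier, path: str | Path) -> dict:
    """Persist a trained model as a directory; returns the manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spec_doc = {
        "format_version": FORMAT_VERSION,
        "model_type": model.model_type,
        "spec": dataclasses.asdict(model.spec),
        "label_vocabulary": model.label_vocabulary,
        "ordered_genes": model.ordered_genes,
    }
    spec_text = json.dumps(spec_doc, indent=1, sort_keys=True)
    weights = model.network.get_weights()
    log_text = _log_to_csv(model.training_log)
    checksum = _content_checksum(spec_text, weights, log_text)
    (path / "spec.json").write_text(spec_text)
    np.savez(path / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
    (path / "training_log.csv").write_text(log_text)
    (path / "checksum.sha256").write_text(checksum + "\n")
    return {"path": str(path), "checksum": checksum, "format_version": FORMAT_VERSION}


def load_model(path: str | Path) -> TrainedClassifier:
    """Load a saved model, verifying format version and content checksum."""
    path = Path(path)
    spec_text = (path / "spec.json").read_text()
    doc = json.loads(spec_text)
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {doc.get('format_version')!r} "
            f"(expected {FORMAT_VERSION})"
        )
    with np.load(path / "weights.npz") as npz:
        weights = [npz[f"w{i}"] for i in range(len(npz.files))]
    log_text = (path / "training_log.csv").read_text()
    stored = (path / "checksum.sha256").read_text().strip()
    actual = _content_checksum(spec_text, weights, log_text)
    if stored != actual:
        raise ValueError(f"model checksum mismatch: stored {stored[:12]}…, actual {actual[:12]}…")
    if doc["model_type"] == "cnn":
        spec: CnnSpec | BpSpec = CnnSpec(**doc["spec"])
        net = _build_cnn(spec, np.random.default_rng(0))
    else:
        spec = BpSpec(**doc["spec"])
        net = _build_bp(spec, np.random.default_rng(0))
    net.set_weights(weights)
    log_df = (
        pd.read_csv(io.StringIO(log_text), float_precision="round_trip")
        if log_text.strip() != "epoch"
        else None
    )
    log = [] if log_df is None else [
        {k: v for k, v in row.items() if pd.notna(v)} for row in log_df.to_dict("records")
    ]
    return TrainedClassifier(spec, net, list(doc["label_vocabulary"]), list(doc["ordered_genes"]), log)
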