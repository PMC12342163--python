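import numpy as np
import pytest

from gprint import evaluation
from gprint.classifiers import PredictionTable
from gprint.evaluation import ConfusionMatrix
from gprint.geneprint import OrderedGeneList, PrintMatrix
from gprint.io_prep import LabelTable


def _pred_from_labels(cells, labels, vocab=None):
    vocab = vocab or sorted(set(labels))
    probs = np.full((len(cells), len(vocab)), 1e-9)
    for i, l in enumerate(labels):
        probs[i, vocab.index(l)] = 1.0
    probs /= probs.sum(axis=1, keepdims=True)
    return PredictionTable(list(cells), probs, list(vocab))


class TestStratifiedSplit:
    def test_balanced_two_class(self):
        cells = [f"c{i}" for i in range(100)]
        labels = LabelTable(cells, ["A"] * 50 + ["B"] * 50)
        train, test = evaluation.stratified_split(labels, 0.7, seed=0)
        mapping = labels.to_dict()
        assert len(train) == 70 and len(test) == 30
        for cls in ("A", "B"):
            assert sum(mapping[c] == cls for c in train) == 35
            assert sum(mapping[c] == cls for c in test) == 15
        assert set(train) | set(test) == set(cells)
        assert set(train) & set(test) == set()

    def test_same_seed_identical(self):
        cells = [f"c{i}" for i in range(40)]
        labels = LabelTable(cells, ["A", "B"] * 20)
        a = evaluation.stratified_split(labels, 0.7, seed=5)
        b = evaluation.stratified_split(labels, 0.7, seed=5)
        assert a == b

    def test_per_class_deviation_at_most_one(self):
        rng = np.random.default_rng(33)
        sizes = [int(rng.integers(2, 41)) for _ in range(6)]
        cells, labels = [], []
        for t, n in enumerate(sizes):
            for i in range(n):
                cells.append(f"t{t}_{i}")
                labels.append(f"T{t}")
        table = LabelTable(cells, labels)
        train, _ = evaluation.stratified_split(table, 0.7, seed=2)
        mapping = table.to_dict()
        for t, n in enumerate(sizes):
            got = sum(mapping[c] == f"T{t}" for c in train)
            assert abs(got - 0.7 * n) <= 1

    def test_singleton_class_to_train_with_warning(self):
        labels = LabelTable(["a", "b", "c"], ["A", "B", "B"])
        with pytest.warns(UserWarning, match="single"):
            train, test = evaluation.stratified_split(labels, 0.7, seed=0)
        assert "a" in train

    def test_invalid_fraction(self):
        labels = LabelTable(["a", "b"], ["A", "B"])
        with pytest.raises(ValueError):
            evaluation.stratified_split(labels, 1.0)


class TestConfusion:
    def test_worked_example(self):
        true = LabelTable(["c1", "c2", "c3"], ["A", "A", "B"])
        pred = _pred_from_labels(["c1", "c2", "c3"], ["A", "B", "B"])
        c = evaluation.confusion(true, pred)
        assert c.labels == ["A", "B"]
        np.testing.assert_array_equal(c.counts, [[1, 1], [0, 1]])

    def test_perfect_prediction_is_diagonal(self):
        cells = [f"c{i}" for i in range(9)]
        labels = ["A", "B", "C"] * 3
        c = evaluation.confusion(LabelTable(cells, labels), _pred_from_labels(cells, labels))
        np.testing.assert_array_equal(c.counts, np.diag([3, 3, 3]))

    def test_tally_oracle_500_pairs(self):
        rng = np.random.default_rng(21)
        cells = [f"c{i}" for i in range(500)]
        vocab = ["w", "x", "y", "z"]
        t = [vocab[i] for i in rng.integers(0, 4, 500)]
        p = [vocab[i] for i in rng.integers(0, 4, 500)]
        c = evaluation.confusion(LabelTable(cells, t), _pred_from_labels(cells, p, vocab))
        for i, ti in enumerate(c.labels):
            for j, pj in enumerate(c.labels):
                expected = sum(1 for a, b in zip(t, p) if a == ti and b == pj)
                assert c.counts[i, j] == expected

    def test_cell_mismatch_error(self):
        true = LabelTable(["c1", "c2"], ["A", "B"])
        pred = _pred_from_labels(["c1", "c3"], ["A", "B"])
        with pytest.raises(ValueError, match="c2|c3"):
            evaluation.confusion(true, pred)


class TestComputeMetrics:
    def test_worked_example(self):
        c = ConfusionMatrix(["pos", "neg"], np.array([[8, 2], [1, 9]]))
        rep = evaluation.compute_metrics(c)
        assert rep.overall_accuracy == pytest.approx(17 / 20)
        assert rep.per_class.loc["pos", "precision"] == pytest.approx(8 / 9)
        assert rep.per_class.loc["pos", "recall"] == pytest.approx(8 / 10)
        assert rep.per_class.loc["pos", "f1"] == pytest.approx(16 / 19)
        assert rep.per_class.loc["pos", "fpr"] == pytest.approx(1 / 10)  # fp=1, tn=9

    def test_diagonal_is_perfect(self):
        c = ConfusionMatrix(["a", "b", "c"], np.diag([4, 5, 6]))
        rep = evaluation.compute_metrics(c)
        assert (rep.per_class[["precision", "recall", "f1"]] == 1.0).all().all()
        assert (rep.per_class["fpr"] == 0.0).all()
        assert rep.overall_accuracy == 1.0

    def test_formula_oracle_random_matrices(self):
        rng = np.random.default_rng(40)
        for _ in range(20):
            counts = rng.integers(0, 30, size=(4, 4))
            c = ConfusionMatrix(["a", "b", "c", "d"], counts)
            total = counts.sum()
            if total == 0:
                continue
            rep = evaluation.compute_metrics(c)
            # independent brute-force evaluation of the six formulas
            for i, label in enumerate(c.labels):
                tp = counts[i][i]
                fn = sum(counts[i]) - tp
                fp = sum(counts[k][i] for k in range(4)) - tp
                tn = total - tp - fn - fp

                def safe(n, d):
                    return n / d if d else 0.0

                row = rep.per_class.loc[label]
                assert row["precision"] == pytest.approx(safe(tp, tp + fp), abs=1e-12)
                assert row["recall"] == pytest.approx(safe(tp, tp + fn), abs=1e-12)
                assert row["f1"] == pytest.approx(safe(2 * tp, 2 * tp + fp + fn), abs=1e-12)
                assert row["tpr"] == row["recall"]
                assert row["fpr"] == pytest.approx(safe(fp, fp + tn), abs=1e-12)
                assert row["accuracy"] == pytest.approx((tp + tn) / total, abs=1e-12)
            assert rep.overall_accuracy == pytest.approx(np.trace(counts) / total, abs=1e-12)
            assert rep.macro_f1 == pytest.approx(rep.per_class["f1"].mean(), abs=1e-12)

    def test_f1_harmonic_mean_identity(self):
        rng = np.random.default_rng(41)
        counts = rng.integers(1, 20, size=(3, 3))
        rep = evaluation.compute_metrics(ConfusionMatrix(["a", "b", "c"], counts))
        for label in ("a", "b", "c"):
            p = rep.per_class.loc[label, "precision"]
            r = rep.per_class.loc[label, "recall"]
            if p + r > 0:
                assert rep.per_class.loc[label, "f1"] == pytest.approx(2 * p * r / (p + r))

    def test_zero_denominator_flagged(self):
        # class "b" never predicted and never true -> precision/recall undefined
        c = ConfusionMatrix(["a", "b"], np.array([[5, 0], [0, 0]]))
        rep = evaluation.compute_metrics(c)
        assert rep.per_class.loc["b", "precision"] == 0.0
        assert "precision" in rep.per_class.loc["b", "undefined"]
        assert "recall" in rep.per_class.loc["b", "undefined"]

    def test_all_metrics_in_unit_interval(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 10, size=(5, 5))
        counts[0, 0] += 1
        rep = evaluation.compute_metrics(ConfusionMatrix(list("abcde"), counts))
        vals = rep.per_class[["precision", "recall", "f1", "tpr", "fpr", "accuracy"]]
        assert ((vals >= 0) & (vals <= 1)).all().all()


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        cells = [f"c{i}" for i in range(10)]
        true = LabelTable(cells, ["A"] * 5 + ["B"] * 5)
        probs = np.column_stack([np.linspace(0.9, 0.0, 10), 1 - np.linspace(0.9, 0.0, 10)])
        pred = PredictionTable(cells, probs, ["A", "B"])
        auc = evaluation.roc_auc(true, pred)
        assert auc["A"] == pytest.approx(1.0)
        assert auc["B"] == pytest.approx(1.0)

    def test_constant_scores_half(self):
        cells = [f"c{i}" for i in range(8)]
        true = LabelTable(cells, ["A", "B"] * 4)
        pred = PredictionTable(cells, np.full((8, 2), 0.5), ["A", "B"])
        auc = evaluation.roc_auc(true, pred)
        assert auc["A"] == pytest.approx(0.5)

    def test_absent_class_is_none(self):
        cells = ["c1", "c2"]
        true = LabelTable(cells, ["A", "A"])
        pred = PredictionTable(cells, np.array([[0.6, 0.4], [0.3, 0.7]]), ["A", "B"])
        auc = evaluation.roc_auc(true, pred)
        assert auc["A"] is None and auc["B"] is None  # one-class truth: no negatives

    def test_pairwise_comparison_oracle(self):
        rng = np.random.default_rng(77)
        n = 200
        cells = [f"c{i}" for i in range(n)]
        truth = [["P", "N"][i] for i in rng.integers(0, 2, n)]
        scores = rng.integers(0, 10, n) / 10.0  # discrete scores force ties
        probs = np.column_stack([1 - scores, scores])
        pred = PredictionTable(cells, probs, ["N", "P"])
        auc = evaluation.roc_auc(LabelTable(cells, truth), pred)
        pos = [s for s, t in zip(scores, truth) if t == "P"]
        neg = [s for s, t in zip(scores, truth) if t == "N"]
        wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
        assert auc["P"] == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)


class _StubModel:
    """kfold trainer stub: predicts via a fixed function of the cell id."""

    def __init__(self, fn, vocab):
        self.fn = fn
        self.vocab = vocab

    def predict(self, prints):
        labels = [self.fn(c) for c in prints.cell_ids]
        return _pred_from_labels(prints.cell_ids, labels, self.vocab)


class TestKfoldCv:
    @staticmethod
    def _data(n=100, classes=("A", "B", "C", "D")):
        rng = np.random.default_rng(1)
        cells = [f"c{i}" for i in range(n)]
        labels = [classes[i % len(classes)] for i in range(n)]
        prints = PrintMatrix(rng.normal(size=(n, 6)), cells,
                             OrderedGeneList([f"g{j}" for j in range(6)]))
        return prints, LabelTable(cells, labels)

    def test_partition_and_fold_sizes(self):
        prints, labels = self._data(100)
        truth = labels.to_dict()
        trainer = lambda p, l: _StubModel(lambda c: truth[c], sorted(set(labels.labels)))
        cv = evaluation.kfold_cv(prints, labels, trainer, k=5, seed=0)
        assert sorted(cv.fold_assignments) == sorted(prints.cell_ids)
        sizes = [sum(1 for f in cv.fold_assignments.values() if f == i) for i in range(5)]
        assert sizes == [20] * 5

    def test_perfect_stub_all_ones(self):
        prints, labels = self._data(60)
        truth = labels.to_dict()
        trainer = lambda p, l: _StubModel(lambda c: truth[c], sorted(set(labels.labels)))
        cv = evaluation.kfold_cv(prints, labels, trainer, k=5, seed=0)
        assert all(r.overall_accuracy == 1.0 for r in cv.fold_reports)
        assert cv.mean["accuracy"] == 1.0 and cv.sd["accuracy"] == 0.0

    def test_random_stub_within_chance_interval(self):
        prints, labels = self._data(400)
        vocab = sorted(set(labels.labels))
        rng = np.random.default_rng(9)
        guess = {c: vocab[i] for c, i in zip(prints.cell_ids, rng.integers(0, 4, 400))}
        trainer = lambda p, l: _StubModel(lambda c: guess[c], vocab)
        cv = evaluation.kfold_cv(prints, labels, trainer, k=5, seed=0)
        lo, hi = evaluation.binomial_chance_interval(400, 0.25, 0.99)
        assert lo <= cv.mean["accuracy"] <= hi

    def test_k_exceeding_cells_is_error(self):
        prints, labels = self._data(4)
        with pytest.raises(ValueError, match="exceeds"):
            evaluation.kfold_cv(prints, labels, lambda p, l: None, k=10)

    def test_small_class_warns(self):
        prints, labels = self._data(12, classes=("A",) * 11 + ("B",))
        truth = labels.to_dict()
        trainer = lambda p, l: _StubModel(lambda c: truth[c], sorted(set(labels.labels)))
        with pytest.warns(UserWarning, match="stratification"):
            evaluation.kfold_cv(prints, labels, trainer, k=5, seed=0)


def test_binomial_chance_interval_contains_p():
    lo, hi = evaluation.binomial_chance_interval(1000, 0.2, 0.99)
    assert lo < 0.2 < hi
    assert 0.15 < lo < 0.2 < hi < 0.25
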