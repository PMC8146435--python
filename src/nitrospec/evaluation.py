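"""Ensemble voting, the repeated 60/30/10 protocol and all evaluation
arithmetic: pooled confusion matrices, CCR, per-class metrics, ROC/AUC,
the paired t-test, and the Kjeldahl total-nitrogen formula.

Metric orientation.  The replicated study tabulates "recall" as
diagonal/column-total and "precision" as diagonal/row-total of a
rows-are-actual confusion matrix — the transpose of the conventional
assignment.  ``per_class_metrics`` reproduces that orientation by default
(``convention="study"``) and offers the textbook one
(``convention="standard"``).  Likewise its "misclassified %" is the row
off-diagonal sum over the *diagonal* cell (not the row total), which can
exceed 100% for a weak classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dataset import SpectralDataset

__all__ = [
    "ConfusionMatrix", "SplitScheme", "TTestResult", "KjeldahlInput",
    "EvaluationReport", "majority_vote", "confusion", "ccr",
    "misclassified_pct", "per_class_metrics", "roc_auc",
    "repeated_evaluation", "paired_t_test", "kjeldahl_nitrogen",
]


# ---------------------------------------------------------------------------
# confusion-matrix arithmetic
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Integer class-by-class counts; rows = actual, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.classes = tuple(str(c) for c in self.classes)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class order")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("class orders differ")
        return ConfusionMatrix(self.counts + other.counts, self.classes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion(actual, predicted, classes) -> ConfusionMatrix:
    """Tally counts[i][j] = #(actual = class i, predicted = class j)."""
    actual = [str(a) for a in actual]
    predicted = [str(p) for p in predicted]
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted differ in length")
    classes = tuple(str(c) for c in classes)
    known = set(classes)
    for name, seq in (("actual", actual), ("predicted", predicted)):
        for lab in seq:
            if lab not in known:
                raise ValueError(f"unknown {name} label {lab!r}")
    if not actual:
        return ConfusionMatrix(np.zeros((len(classes), len(classes)), int),
                               classes)
    counts = _sk_confusion(actual, predicted, labels=list(classes))
    return ConfusionMatrix(counts, classes)


def ccr(matrix: ConfusionMatrix) -> float:
    """Correct classification rate: 100 · trace / grand total."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(matrix.counts)) / matrix.total


def misclassified_pct(matrix: ConfusionMatrix, cls) -> float:
    """Row off-diagonal sum over the diagonal cell, in percent.

    This is the study tables' convention; it is *not* bounded by 100.
    """
    i = matrix.classes.index(str(cls))
    diag = matrix.counts[i, i]
    if diag == 0:
        raise ValueError(f"zero diagonal for class {cls!r}")
    off = matrix.counts[i].sum() - diag
    return 100.0 * float(off) / float(diag)


def per_class_metrics(matrix: ConfusionMatrix,
                      convention: str = "study") -> pd.DataFrame:
    """Recall/accuracy/specificity/precision/F per class, in percent.

    ``convention="study"`` assigns FN = column total − diagonal and
    FP = row total − diagonal (the orientation of the replicated report);
    ``"standard"`` swaps them.
    """
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    if convention not in ("study", "standard"):
        raise ValueError("convention must be 'study' or 'standard'")
    counts = matrix.counts.astype(float)
    total = counts.sum()
    rows = []
    for i, cls in enumerate(matrix.classes):
        tp = counts[i, i]
        row_rest = counts[i].sum() - tp
        col_rest = counts[:, i].sum() - tp
        if convention == "study":
            fn, fp = col_rest, row_rest
        else:
            fn, fp = row_rest, col_rest
        tn = total - tp - fp - fn

        def ratio(num, den, name):
            if den == 0:
                warnings.warn(f"{name} undefined for class {cls}; reporting 0")
                return 0.0
            return 100.0 * num / den

        recall = ratio(tp, tp + fn, "recall")
        precision = ratio(tp, tp + fp, "precision")
        accuracy = ratio(tp + tn, total, "accuracy")
        specificity = ratio(tn, tn + fp, "specificity")
        f = (2 * recall * precision / (recall + precision)
             if recall + precision > 0 else 0.0)
        rows.append({"recall": recall, "accuracy": accuracy,
                     "specificity": specificity, "precision": precision,
                     "f": f})
    return pd.DataFrame(rows, index=list(matrix.classes))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, positive_mask):
    """One-vs-rest ROC by threshold sweep; AUC by the trapezoidal rule.

    Tied scores follow the midrank convention, so the AUC equals the
    Mann–Whitney U statistic divided by n₁·n₂.  Returns
    ``(auc, fpr, tpr)``.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(positive_mask).ravel().astype(bool)
    if scores.size != y.size:
        raise ValueError("scores and labels differ in length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(y.astype(int), scores)
    return float(np.trapezoid(tpr, fpr)), fpr, tpr


# ---------------------------------------------------------------------------
# majority voting
# ---------------------------------------------------------------------------

def majority_vote(votes, scores, classes) -> np.ndarray:
    """Plurality label per sample from several classifiers.

    ``votes`` is a sequence of per-classifier label arrays, ``scores`` a
    matching sequence of (n, n_classes) normalised score matrices.  Ties
    are broken by (1) the highest summed score among the tied classes,
    then (2) class order.
    """
    if len(votes) == 0:
        raise ValueError("majority voting needs at least one voter")
    classes = tuple(str(c) for c in classes)
    index = {c: i for i, c in enumerate(classes)}
    votes = [np.asarray([str(v) for v in arr], dtype=object) for arr in votes]
    n = votes[0].size
    if any(v.size != n for v in votes):
        raise ValueError("voters disagree on sample count")
    counts = np.zeros((n, len(classes)))
    for arr in votes:
        for r, lab in enumerate(arr):
            counts[r, index[lab]] += 1
    summed = np.sum(scores, axis=0) if scores is not None else np.zeros_like(counts)
    out = np.empty(n, dtype=object)
    for r in range(n):
        top = counts[r].max()
        tied = np.nonzero(counts[r] == top)[0]
        if tied.size > 1:
            best = summed[r, tied].max()
            tied = tied[summed[r, tied] == best]
        out[r] = classes[tied[0]]
    return out


# ---------------------------------------------------------------------------
# the repeated 60/30/10 protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitScheme:
    """Repeated random-split protocol: 60% train / 30% test / 10% validation."""

    train: float = 0.6
    test: float = 0.3
    validation: float = 0.1
    iterations: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if min(self.train, self.test, self.validation) < 0:
            raise ValueError("fractions must be non-negative")
        if abs(self.train + self.test + self.validation - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")

    def split(self, n: int, rng: np.random.Generator):
        perm = rng.permutation(n)
        n_train = int(round(self.train * n))
        n_test = int(round(self.test * n))
        return (perm[:n_train], perm[n_train:n_train + n_test],
                perm[n_train + n_test:])


@dataclass
class EvaluationReport:
    """Pooled matrices and per-iteration series from a repeated evaluation."""

    classes: tuple[str, ...]
    pooled: dict[str, ConfusionMatrix]
    ccr_series: dict[str, np.ndarray]
    auc_series: dict[str, np.ndarray]   # (iterations, n_classes)
    iterations: int

    def pooled_ccr(self) -> dict[str, float]:
        return {name: ccr(cm) for name, cm in self.pooled.items()}

    def confusion_table(self) -> pd.DataFrame:
        """All pooled matrices in one long table: per classifier and actual
        class, the predicted-class counts, the row total, the
        misclassified % and the classifier's CCR."""
        rows = []
        for name, cm in self.pooled.items():
            for i, cls in enumerate(self.classes):
                row = {"classifier": name, "actual": cls}
                row.update({p: int(cm.counts[i, j])
                            for j, p in enumerate(self.classes)})
                row["total"] = int(cm.counts[i].sum())
                row["misclassified_pct"] = (
                    round(misclassified_pct(cm, cls), 2)
                    if cm.counts[i, i] else float("nan"))
                row["ccr"] = round(ccr(cm), 2)
                rows.append(row)
        return pd.DataFrame(rows)

    def metrics_table(self, convention: str = "study") -> pd.DataFrame:
        """Per-classifier, per-class metric table (percent)."""
        frames = []
        for name, cm in self.pooled.items():
            t = per_class_metrics(cm, convention=convention)
            t.insert(0, "classifier", name)
            frames.append(t.reset_index(names="class"))
        return pd.concat(frames, ignore_index=True)

    def mean_auc(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: series.mean(axis=0)
             for name, series in self.auc_series.items()},
            index=list(self.classes)).T


def repeated_evaluation(dataset: SpectralDataset, classifier_factory,
                        scheme: SplitScheme = SplitScheme()) -> EvaluationReport:
    """Run the repeated-split protocol over the five-member ensemble.

    ``classifier_factory(seed)`` must return a fresh mapping of classifier
    name → unfitted :class:`~nitrospec.classifiers.TrainedClassifier`.
    Per iteration: a seeded shuffle and 60/30/10 split, every classifier
    fitted on the training share (validation share available for model
    selection), test-share predictions pooled into one confusion matrix
    per classifier plus the majority vote ("MV", whose ROC scores are the
    mean of the members' normalised scores).  A split missing a class in
    training is reseeded once, then raises.
    """
    scheme.validate()
    classes = dataset.classes
    if len(classes) < 2:
        raise ValueError("repeated evaluation needs at least two classes")
    n = dataset.n_samples
    names = None
    pooled: dict[str, ConfusionMatrix] = {}
    ccr_series: dict[str, list] = {}
    auc_series: dict[str, list] = {}

    for it in range(scheme.iterations):
        # a split missing a class in train or test is reseeded once
        for attempt in (0, 1):
            rng = np.random.default_rng(
                np.random.SeedSequence([scheme.seed, it, attempt]))
            train, test, val = scheme.split(n, rng)
            y_train = set(map(str, dataset.labels[train]))
            y_test = set(map(str, dataset.labels[test]))
            if y_train == set(classes) and y_test == set(classes):
                break
        if set(map(str, dataset.labels[train])) != set(classes):
            raise ValueError(
                f"iteration {it}: a split is missing a class even after "
                "reseeding; dataset too small for the protocol")
        it_seed = int(rng.integers(2 ** 31))
        members = classifier_factory(it_seed)
        if names is None:
            names = list(members) + ["MV"]
            for name in names:
                pooled[name] = ConfusionMatrix(
                    np.zeros((len(classes), len(classes)), int), classes)
                ccr_series[name] = []
                auc_series[name] = []

        X = dataset.values
        y = dataset.labels
        y_test_arr = np.asarray([str(v) for v in y[test]], dtype=object)
        votes, score_stack = [], []
        for name, clf in members.items():
            clf.fit(X[train], y[train], X[val], y[val])
            scores = clf.predict_scores(X[test])
            # align score columns to the dataset class order
            aligned = np.zeros((scores.shape[0], len(classes)))
            for j, c in enumerate(clf.classes_):
                aligned[:, classes.index(c)] = scores[:, j]
            pred = clf.predict(X[test])
            votes.append(pred)
            score_stack.append(aligned)
            cm = confusion(y_test_arr, pred, classes)
            pooled[name] = pooled[name] + cm
            ccr_series[name].append(ccr(cm))
            auc_series[name].append(_per_class_auc(aligned, y_test_arr, classes))
        mv_pred = majority_vote(votes, score_stack, classes)
        mv_scores = np.mean(score_stack, axis=0)
        cm = confusion(y_test_arr, mv_pred, classes)
        pooled["MV"] = pooled["MV"] + cm
        ccr_series["MV"].append(ccr(cm))
        auc_series["MV"].append(_per_class_auc(mv_scores, y_test_arr, classes))

    return EvaluationReport(
        classes=classes, pooled=pooled,
        ccr_series={k: np.asarray(v) for k, v in ccr_series.items()},
        auc_series={k: np.asarray(v) for k, v in auc_series.items()},
        iterations=scheme.iterations)


def _per_class_auc(scores, y_true, classes):
    out = []
    for j, c in enumerate(classes):
        mask = y_true == c
        if mask.all() or not mask.any():
            out.append(np.nan)
        else:
            out.append(roc_auc(scores[:, j], mask)[0])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# paired t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    mean_difference: float
    sd_difference: float
    t: float
    df: int
    p: float


def paired_t_test(values_a, values_b) -> TTestResult:
    """Two-sided paired t-test on matched value sequences (d = a − b)."""
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = d.size - 1
    if sd == 0.0:
        # exact-difference report: identical pairs mean no evidence at all;
        # a constant non-zero difference is a sure one
        if mean == 0.0:
            return TTestResult(0.0, 0.0, 0.0, df, 1.0)
        return TTestResult(mean, 0.0, float(np.sign(mean) * np.inf), df, 0.0)
    t = mean / (sd / np.sqrt(d.size))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(mean, sd, float(t), df, p)


# ---------------------------------------------------------------------------
# Kjeldahl total nitrogen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KjeldahlInput:
    """Titration bookkeeping for the Kjeldahl total-nitrogen assay.

    ``vs``/``vb``: acid volumes (mL) consumed by the sample and the blank;
    ``normality``: sulphuric-acid normality (eq/L); ``md``: dry mass (g).
    """

    vs: float
    vb: float
    normality: float
    md: float


def kjeldahl_nitrogen(inp: KjeldahlInput) -> float:
    """Percent total nitrogen: 100 · ((Vs − Vb)/md) · N_H2SO4 · 0.014."""
    if inp.md <= 0:
        raise ValueError("dry mass must be positive")
    if inp.vs < 0 or inp.vb < 0:
        raise ValueError("volumes must be non-negative")
    if inp.vs < inp.vb:
        warnings.warn("blank titration exceeds sample; negative nitrogen")
    return 100.0 * ((inp.vs - inp.vb) / inp.md) * inp.normality * 0.014
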