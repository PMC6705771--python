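"""Multinomial Naive Bayes classification and the evaluation harness.

The classifier is a standard multinomial Naive Bayes with additive
(Laplace) smoothing computed in log space over bag-of-words counts.
Evaluation reports precision TP/(TP+FP), recall TP/(TP+FN), their
harmonic mean F = 2PR/(P+R) and accuracy; zero-denominator cases are
reported as undefined (None), never coerced to 0 or 1.  Cross-validation
is stratified k-fold (default k=10) with a seeded partition; a 40/60
split and a literal five-half-sub-samples mode are available as
alternative protocols.  ROC points come from sweeping the decision
threshold over the positive-class posteriors.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse

log = logging.getLogger(__name__)


class ClassifyError(ValueError):
    pass


@dataclass
class NBModel:
    classes: list[str]
    log_prior: np.ndarray  # (n_classes,)
    log_likelihood: np.ndarray  # (n_classes, n_features)
    alpha: float
    vocabulary_ref: tuple
    negative_label: str

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "fusemine-nb",
            "version": 1,
            "classes": self.classes,
            "log_prior": self.log_prior.tolist(),
            "log_likelihood": self.log_likelihood.tolist(),
            "alpha": self.alpha,
            "vocabulary": [list(g) if isinstance(g, tuple) else g
                           for g in self.vocabulary_ref],
            "negative_label": self.negative_label,
        }
        Path(path).write_text(
            json.dumps(payload, indent=2) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "NBModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "fusemine-nb":
            raise ClassifyError(f"{path} is not a serialized NB model")
        return cls(
            classes=payload["classes"],
            log_prior=np.asarray(payload["log_prior"]),
            log_likelihood=np.asarray(payload["log_likelihood"]),
            alpha=payload["alpha"],
            vocabulary_ref=tuple(
                tuple(g) if isinstance(g, list) else g
                for g in payload["vocabulary"]
            ),
            negative_label=payload["negative_label"],
        )


@dataclass
class EvalReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    precision: float | None = None
    recall: float | None = None
    f_score: float | None = None
    accuracy: float | None = None
    per_fold: list[dict] = field(default_factory=list)
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn,
            "precision": self.precision, "recall": self.recall,
            "f_score": self.f_score, "accuracy": self.accuracy,
            "auc": self.auc, "per_fold": self.per_fold,
            "roc_points": [list(p) for p in self.roc_points],
        }

    def write(self, base: str | Path) -> None:
        base = Path(base)
        base.with_suffix(".json").write_text(
            json.dumps(self.to_dict(), indent=2) + "\n", encoding="utf-8"
        )
        def fmt(x):
            return "undefined" if x is None else f"{x:.6f}"
        lines = [
            "metric\tvalue",
            f"TP\t{self.tp}", f"FP\t{self.fp}",
            f"FN\t{self.fn}", f"TN\t{self.tn}",
            f"precision\t{fmt(self.precision)}",
            f"recall\t{fmt(self.recall)}",
            f"f_score\t{fmt(self.f_score)}",
            f"accuracy\t{fmt(self.accuracy)}",
            f"auc\t{fmt(self.auc)}",
        ]
        base.with_suffix(".tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
        if self.roc_points:
            roc = ["fpr\ttpr"] + [
                f"{fpr:.6f}\t{tpr:.6f}" for fpr, tpr in self.roc_points
            ]
            base.with_suffix(".roc.tsv").write_text(
                "\n".join(roc) + "\n", encoding="utf-8"
            )


def _as_dense(X) -> np.ndarray:
    if sparse.issparse(X):
        return np.asarray(X.todense())
    return np.atleast_2d(np.asarray(X, dtype=float))


def train_nb(
    X,
    labels: list[str],
    alpha: float = 1.0,
    vocabulary_ref: tuple = (),
    negative_label: str | None = None,
) -> NBModel:
    """Fit a multinomial Naive Bayes model with Laplace smoothing.

    Likelihoods are (class gram count + alpha) / (class total + alpha*V),
    stored in log space.  Requires at least one example per class and a
    strictly positive alpha.
    """
    if alpha <= 0:
        raise ClassifyError(f"alpha must be > 0, got {alpha}")
    X = _as_dense(X)
    labels = list(labels)
    if X.shape[0] != len(labels):
        raise ClassifyError("row count does not match label count")
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ClassifyError("training data contains a single class")
    n_features = X.shape[1]
    log_prior = np.empty(len(classes))
    log_likelihood = np.empty((len(classes), n_features))
    y = np.asarray(labels)
    for ci, cls in enumerate(classes):
        mask = y == cls
        log_prior[ci] = math.log(mask.sum() / len(labels))
        counts = X[mask].sum(axis=0)
        total = counts.sum()
        log_likelihood[ci] = np.log(
            (counts + alpha) / (total + alpha * n_features)
        )
    if negative_label is None:
        negative_label = classes[0]
    return NBModel(
        classes=classes,
        log_prior=log_prior,
        log_likelihood=log_likelihood,
        alpha=alpha,
        vocabulary_ref=tuple(vocabulary_ref) or tuple(range(n_features)),
        negative_label=negative_label,
    )


def predict_nb(
    model: NBModel, feature_vector, vocabulary_ref: tuple | None = None
) -> tuple[str, dict[str, float]]:
    """Predict one example: argmax of log prior + sum count*log likelihood.

    Posteriors are normalized to sum to one; exact posterior ties resolve
    to the model's negative class.  A vector from a different vocabulary
    is rejected.
    """
    x = _as_dense(feature_vector).ravel()
    if vocabulary_ref is not None and tuple(vocabulary_ref) != model.vocabulary_ref:
        raise ClassifyError("feature vector comes from a different vocabulary")
    if x.shape[0] != model.log_likelihood.shape[1]:
        raise ClassifyError(
            f"vector length {x.shape[0]} does not match vocabulary size "
            f"{model.log_likelihood.shape[1]}"
        )
    joint = model.log_prior + model.log_likelihood @ x
    joint -= joint.max()
    post = np.exp(joint)
    post /= post.sum()
    posteriors = dict(zip(model.classes, post.tolist()))
    best = max(post)
    tied = [c for c, p in zip(model.classes, post) if math.isclose(p, best, rel_tol=0, abs_tol=1e-12)]
    if len(tied) > 1 and model.negative_label in tied:
        label = model.negative_label
    else:
        label = model.classes[int(np.argmax(post))]
    return label, posteriors


def predict_many(model: NBModel, X) -> tuple[list[str], np.ndarray]:
    """Vectorized prediction; returns labels and the posterior matrix."""
    X = _as_dense(X)
    joint = model.log_prior[None, :] + X @ model.log_likelihood.T
    joint -= joint.max(axis=1, keepdims=True)
    post = np.exp(joint)
    post /= post.sum(axis=1, keepdims=True)
    labels = []
    neg_idx = model.classes.index(model.negative_label)
    for row in post:
        best = row.max()
        if math.isclose(row[neg_idx], best, rel_tol=0, abs_tol=1e-12):
            labels.append(model.negative_label)
        else:
            labels.append(model.classes[int(row.argmax())])
    return labels, post


# -- metrics -------------------------------------------------------------

def evaluate(
    true_labels: list[str],
    predicted_labels: list[str],
    positive_label: str,
) -> EvalReport:
    """Confusion counts plus precision / recall / F-score / accuracy.

    Zero-denominator metrics are reported as None ("undefined"), distinct
    from 0.
    """
    if len(true_labels) != len(predicted_labels):
        raise ClassifyError("label sequences differ in length")
    tp = fp = fn = tn = 0
    for t, p in zip(true_labels, predicted_labels):
        if p == positive_label:
            if t == positive_label:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive_label:
                fn += 1
            else:
                tn += 1
    return _report_from_counts(tp, fp, fn, tn)


def _report_from_counts(tp: int, fp: int, fn: int, tn: int) -> EvalReport:
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision is not None and recall is not None and precision + recall > 0:
        f_score = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f_score = 0.0
    else:
        f_score = None
    total = tp + fp + fn + tn
    accuracy = (tp + tn) / total if total else None
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=precision, recall=recall,
        f_score=f_score, accuracy=accuracy,
    )


def token_agreement_score(
    gold_tokens: list[str], predicted_tokens: list[str]
) -> float:
    """Positional agreement between gold and predicted token labels.

    Labels are drawn from {n, y, a} (no token / token instance / noise);
    the score is the fraction of positions where the prediction equals
    the gold label.
    """
    if len(gold_tokens) != len(predicted_tokens):
        raise ClassifyError("token sequences differ in length")
    allowed = {"n", "y", "a"}
    if not set(gold_tokens) <= allowed or not set(predicted_tokens) <= allowed:
        raise ClassifyError("token labels must be drawn from {n, y, a}")
    if not gold_tokens:
        raise ClassifyError("token sequences must be non-empty")
    hits = sum(g == p for g, p in zip(gold_tokens, predicted_tokens))
    return hits / len(gold_tokens)


# -- cross-validation ----------------------------------------------------

def _stratified_folds(
    labels: list[str], k: int, seed: int
) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    counter = 0  # rotates across classes so fold sizes stay balanced
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for example in idx:
            folds[counter % k].append(int(example))
            counter += 1
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def cross_validate(
    X,
    labels: list[str],
    positive_label: str,
    k: int = 10,
    seed: int = 0,
    alpha: float = 1.0,
) -> EvalReport:
    """Stratified k-fold cross-validation of the Naive Bayes model.

    The folds partition the data (each example is tested exactly once);
    the seed fixes the partition.  Folds whose training part lacks a
    class are skipped with a warning.  Reports pooled confusion counts
    and metrics, a per-fold breakdown, and the pooled ROC.
    """
    if k < 2:
        raise ClassifyError("k must be >= 2")
    labels = list(labels)
    if len(labels) < k:
        raise ClassifyError("need at least k examples")
    X = _as_dense(X)
    folds = _stratified_folds(labels, k, seed)
    y = np.asarray(labels)
    pooled = EvalReport()
    pos_scores: list[float] = []
    pos_truth: list[str] = []
    for fold_no, test_idx in enumerate(folds):
        if len(test_idx) == 0:
            continue
        train_mask = np.ones(len(labels), dtype=bool)
        train_mask[test_idx] = False
        train_labels = y[train_mask].tolist()
        if len(set(train_labels)) < 2:
            log.warning("fold %d skipped: single-class training data", fold_no)
            continue
        model = train_nb(X[train_mask], train_labels, alpha=alpha)
        predicted, post = predict_many(model, X[test_idx])
        truth = y[test_idx].tolist()
        fold_report = evaluate(truth, predicted, positive_label)
        pooled.tp += fold_report.tp
        pooled.fp += fold_report.fp
        pooled.fn += fold_report.fn
        pooled.tn += fold_report.tn
        pooled.per_fold.append(
            {"fold": fold_no, **{k_: v for k_, v in fold_report.to_dict().items()
                                 if k_ not in ("per_fold", "roc_points")}}
        )
        pos_col = model.classes.index(positive_label)
        pos_scores.extend(post[:, pos_col].tolist())
        pos_truth.extend(truth)
    summary = _report_from_counts(pooled.tp, pooled.fp, pooled.fn, pooled.tn)
    pooled.precision = summary.precision
    pooled.recall = summary.recall
    pooled.f_score = summary.f_score
    pooled.accuracy = summary.accuracy
    if len(set(pos_truth)) == 2:
        pooled.roc_points, pooled.auc = roc_curve(
            pos_truth, pos_scores, positive_label
        )
    return pooled


def split_40_60(labels: list[str], seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 40% train / 60% test split (alternative protocol)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(labels)
    train, test = [], []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        cut = int(round(0.4 * len(idx)))
        train.extend(idx[:cut])
        test.extend(idx[cut:])
    return np.asarray(sorted(train)), np.asarray(sorted(test))


def split_halves(labels: list[str], seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Ten equal sub-samples, five for model building and five for
    testing (alternative protocol)."""
    folds = _stratified_folds(list(labels), 10, seed)
    train = np.concatenate(folds[:5])
    test = np.concatenate(folds[5:])
    return np.sort(train), np.sort(test)


# -- ROC -----------------------------------------------------------------

def roc_curve(
    true_labels: list[str],
    positive_posteriors: list[float],
    positive_label: str,
) -> tuple[list[tuple[float, float]], float]:
    """ROC points from sweeping the decision threshold, plus trapezoid AUC.

    Thresholds sweep all distinct posterior values plus {0, 1}; the curve
    starts at (0, 0), ends at (1, 1) and is non-decreasing in both
    coordinates.
    """
    if len(true_labels) != len(positive_posteriors):
        raise ClassifyError("label and posterior sequences differ in length")
    scores = np.asarray(positive_posteriors, dtype=float)
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ClassifyError("posteriors must lie in [0, 1]")
    truth = np.asarray([t == positive_label for t in true_labels])
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ClassifyError("ROC requires both classes in the truth labels")
    thresholds = np.unique(np.concatenate([scores, [0.0, 1.0]]))[::-1]
    points = [(0.0, 0.0)]
    for thr in thresholds:
        predicted_pos = scores >= thr
        tpr = float((predicted_pos & truth).sum() / n_pos)
        fpr = float((predicted_pos & ~truth).sum() / n_neg)
        if (fpr, tpr) != points[-1]:
            points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    auc = float(
        np.trapezoid(
            [p[1] for p in points], [p[0] for p in points]
        )
    )
    return points, auc
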