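"""Diagnostic classification issues, cross-validation and scoring.

Five diagnostic *issues* are evaluated, mirroring the clinically
interesting contrasts between the three cohort classes:

=====  =====================================================
I      neurotypical vs mild AD (binary)
II     neurotypical vs moderate AD (binary)
III    mild AD vs moderate AD (binary)
IV     neurotypical vs mild-and-moderate AD merged (binary)
V      neurotypical vs mild AD vs moderate AD (three-class)
=====  =====================================================

Two cross-validation schemes are supported:

* ``kfold`` — stratified 10-fold at the trial level.  Trials of one
  subject can land on both sides of a split; that subject-level leakage
  is a property of pooling trials and is kept deliberately, since the
  subject-safe alternative is the second scheme.
* ``loso`` — subject-grouped folds: within each class, subjects are
  partitioned into ``round(1/holdout_fraction)`` groups (default 20%,
  i.e. grouped 5-fold), and no subject's trials ever cross the
  train/test boundary.  Setting the fraction to ``1/n_subjects`` gives
  literal leave-one-subject-out.

Binary metrics are percentage precision TP/(TP+FP), recall TP/(TP+FN)
and accuracy (TP+TN)/total; the three-class issue reports macro-averaged
one-vs-rest precision/recall and trace accuracy.  Per-fold metrics are
averaged unweighted; degenerate folds are skipped and counted, never
silently averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classify import FoldSkip, fit_predict
from .features import FeatureMatrix

ISSUES = ("I", "II", "III", "IV", "V")

_ISSUE_CLASSES = {
    "I": ("neurotypical", "mild_ad"),
    "II": ("neurotypical", "moderate_ad"),
    "III": ("mild_ad", "moderate_ad"),
    "IV": ("neurotypical", "mild_ad", "moderate_ad"),
    "V": ("neurotypical", "mild_ad", "moderate_ad"),
}

#: Positive (disease) class per binary issue; None for the 3-class issue.
ISSUE_POSITIVE = {"I": "mild_ad", "II": "moderate_ad", "III": "moderate_ad",
                  "IV": "ad", "V": None}


class PlanningError(ValueError):
    """A cross-validation plan cannot be constructed for this cohort."""


def make_issue_dataset(fm: FeatureMatrix, issue: str):
    """Restrict/relabel a feature matrix for one diagnostic issue.

    Returns ``(FeatureMatrix, positive_class)``; for issue IV the two AD
    classes are merged into one positive class labelled ``"ad"``.
    """
    if issue not in ISSUES:
        raise ValueError(f"unknown issue {issue!r}")
    wanted = _ISSUE_CLASSES[issue]
    present = set(fm.labels)
    missing = [c for c in wanted if c not in present]
    if missing:
        raise ValueError(f"issue {issue} requires missing class(es): {missing}")
    keep = np.array([lbl in wanted for lbl in fm.labels])
    labels = tuple(np.array(fm.labels)[keep])
    if issue == "IV":
        labels = tuple("ad" if lbl != "neurotypical" else lbl for lbl in labels)
    sub = FeatureMatrix(
        values=fm.values[keep],
        feature_name=fm.feature_name,
        column_labels=fm.column_labels,
        labels=labels,
        subject_ids=tuple(np.array(fm.subject_ids)[keep]),
    )
    return sub, ISSUE_POSITIVE[issue]


@dataclass
class CVPlan:
    scheme: str                  # "kfold" | "loso"
    folds: list                  # of (train_idx, test_idx) ndarray pairs
    k: int
    seed: int


def plan_cv(
    fm: FeatureMatrix,
    scheme: str = "kfold",
    k: int = 10,
    seed: int = 0,
    loso_holdout_fraction: float = 0.20,
) -> CVPlan:
    """Build fold assignments for one feature matrix.

    ``kfold`` stratifies trials by class; ``loso`` partitions subjects
    within each class into ``round(1/loso_holdout_fraction)`` groups and
    holds out one group per class per fold.
    """
    y = np.asarray(fm.labels)
    if scheme == "kfold":
        if fm.n_trials < k:
            raise PlanningError(f"{fm.n_trials} trials cannot form {k} folds")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(tr, te) for tr, te in skf.split(fm.values, y)]
        return CVPlan(scheme="kfold", folds=folds, k=k, seed=seed)
    if scheme != "loso":
        raise ValueError(f"unknown scheme {scheme!r}")

    n_folds = int(round(1.0 / loso_holdout_fraction))
    rng = np.random.default_rng(seed)
    subj = np.asarray(fm.subject_ids)
    subj_class = {}
    for s, lbl in zip(subj, y):
        subj_class[s] = lbl
    fold_of_subject = {}
    for lbl in sorted(set(y)):
        members = sorted(s for s, c in subj_class.items() if c == lbl)
        if len(members) < n_folds:
            raise PlanningError(
                f"class {lbl!r} has {len(members)} subjects, fewer than the "
                f"{n_folds} holdout groups a {loso_holdout_fraction:.0%} "
                "fraction requires"
            )
        order = rng.permutation(len(members))
        for pos, mi in enumerate(order):
            fold_of_subject[members[mi]] = pos % n_folds
    folds = []
    for f in range(n_folds):
        test = np.flatnonzero([fold_of_subject[s] == f for s in subj])
        train = np.flatnonzero([fold_of_subject[s] != f for s in subj])
        folds.append((train, test))
    return CVPlan(scheme="loso", folds=folds, k=n_folds, seed=seed)


@dataclass
class ConfusionCounts:
    """Binary TP/FP/TN/FN, or a K x K count matrix for multi-class."""

    matrix: np.ndarray           # K x K, rows = true, cols = predicted
    classes: tuple
    positive_class: str | None = None

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def binary_counts(self) -> tuple:
        if self.positive_class is None or len(self.classes) != 2:
            raise ValueError("binary counts need a 2-class task with a positive class")
        p = self.classes.index(self.positive_class)
        n = 1 - p
        m = self.matrix
        return int(m[p, p]), int(m[n, p]), int(m[n, n]), int(m[p, n])  # TP FP TN FN


def score(y_true, y_pred, positive_class: str | None = None, classes=None):
    """Confusion counts plus percentage precision/recall/accuracy.

    Binary tasks use the positive class directly; multi-class tasks
    macro-average one-vs-rest precision and recall, with accuracy as the
    fraction of the confusion-matrix trace.  An undefined precision
    (no positive predictions) counts as 0 and is flagged.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    if classes is None:
        classes = tuple(sorted(set(y_true) | set(y_pred)))
    else:
        classes = tuple(classes)
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    counts = ConfusionCounts(matrix=m, classes=classes, positive_class=positive_class)

    flags = []
    if positive_class is not None and k == 2:
        tp, fp, tn, fn = counts.binary_counts()
        if tp + fp == 0:
            precision = 0.0
            flags.append("undefined_precision")
        else:
            precision = tp / (tp + fp) * 100.0
        recall = (tp / (tp + fn) * 100.0) if tp + fn else 0.0
        accuracy = (tp + tn) / counts.total * 100.0
    else:
        precisions, recalls = [], []
        for i in range(k):
            tp = m[i, i]
            fp = m[:, i].sum() - tp
            fn = m[i, :].sum() - tp
            if tp + fp == 0:
                precisions.append(0.0)
                flags.append("undefined_precision")
            else:
                precisions.append(tp / (tp + fp) * 100.0)
            recalls.append((tp / (tp + fn) * 100.0) if tp + fn else 0.0)
        precision = float(np.mean(precisions))
        recall = float(np.mean(recalls))
        accuracy = float(np.trace(m)) / counts.total * 100.0
    metrics = {"precision": precision, "recall": recall, "accuracy": accuracy,
               "flags": flags}
    return counts, metrics


@dataclass
class EvaluationRecord:
    """One (issue, feature, classifier, CV scheme) results cell."""

    issue: str
    feature_name: str
    classifier_kind: str
    cv_scheme: str
    precision: float
    recall: float
    accuracy: float
    per_fold: list = field(default_factory=list)
    n_skipped_folds: int = 0


def evaluate_matrix(
    fm: FeatureMatrix,
    issue: str,
    configs: list,
    schemes=("kfold", "loso"),
    k: int = 10,
    seed: int = 0,
    loso_holdout_fraction: float = 0.20,
) -> list:
    """Cross-validate every classifier config on one feature matrix."""
    sub, positive = make_issue_dataset(fm, issue)
    classes = tuple(sorted(set(sub.labels)))
    y = np.asarray(sub.labels)
    records = []
    for scheme in schemes:
        plan = plan_cv(sub, scheme=scheme, k=k, seed=seed,
                       loso_holdout_fraction=loso_holdout_fraction)
        for config in configs:
            fold_metrics, skipped = [], 0
            for train, test in plan.folds:
                try:
                    pred = fit_predict(config, sub.values[train], y[train],
                                       sub.values[test])
                except FoldSkip:
                    skipped += 1
                    continue
                _, metrics = score(y[test], pred, positive_class=positive,
                                   classes=classes)
                fold_metrics.append(metrics)
            if not fold_metrics:
                raise PlanningError(
                    f"every fold degenerate for issue {issue} / {scheme}"
                )
            records.append(
                EvaluationRecord(
                    issue=issue,
                    feature_name=sub.feature_name,
                    classifier_kind=config.kind,
                    cv_scheme=scheme,
                    precision=float(np.mean([m["precision"] for m in fold_metrics])),
                    recall=float(np.mean([m["recall"] for m in fold_metrics])),
                    accuracy=float(np.mean([m["accuracy"] for m in fold_metrics])),
                    per_fold=fold_metrics,
                    n_skipped_folds=skipped,
                )
            )
    return records


def run_issue(
    feature_matrices: dict,
    issue: str,
    configs: list,
    schemes=("kfold", "loso"),
    k: int = 10,
    seed: int = 0,
    loso_holdout_fraction: float = 0.20,
) -> list:
    """Evaluate one issue over several feature types.

    ``feature_matrices`` maps feature name -> :class:`FeatureMatrix` for
    the same cohort; the result holds one record per (feature,
    classifier, scheme).
    """
    records = []
    for name in feature_matrices:
        records.extend(
            evaluate_matrix(
                feature_matrices[name], issue, configs, schemes=schemes, k=k,
                seed=seed, loso_holdout_fraction=loso_holdout_fraction,
            )
        )
    return records


def report(records: list) -> dict:
    """Pivot records into one table per (issue, scheme).

    Each table has one row per feature and a (classifier, metric) column
    pair grid — the precision/recall/accuracy triplet layout results of
    this kind are conventionally presented in.
    """
    tables = {}
    keys = sorted({(r.issue, r.cv_scheme) for r in records})
    for issue, scheme in keys:
        rows = {}
        for r in records:
            if (r.issue, r.cv_scheme) != (issue, scheme):
                continue
            row = rows.setdefault(r.feature_name, {})
            row[(r.classifier_kind, "Pre.")] = r.precision
            row[(r.classifier_kind, "Rec.")] = r.recall
            row[(r.classifier_kind, "Acc.")] = r.accuracy
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        df.index.name = "feature"
        tables[(issue, scheme)] = df.sort_index()
    if not records:
        tables[("", "")] = pd.DataFrame()
    return tables


def best_combinations(records: list) -> pd.DataFrame:
    """Per-issue best (feature, classifier, scheme) by accuracy."""
    rows = []
    for issue in sorted({r.issue for r in records}):
        best = max((r for r in records if r.issue == issue),
                   key=lambda r: r.accuracy)
        rows.append({
            "issue": issue,
            "feature": best.feature_name,
            "classifier": best.classifier_kind,
            "cv_scheme": best.cv_scheme,
            "precision": best.precision,
            "recall": best.recall,
            "accuracy": best.accuracy,
        })
    return pd.DataFrame(rows)


def write_report(records: list, directory) -> list:
    """Write one CSV per (issue, scheme) plus a best-combination summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for (issue, scheme), df in report(records).items():
        name = f"issue_{issue}_{scheme}.csv" if issue else "empty.csv"
        df.to_csv(directory / name)
        written.append(directory / name)
    if records:
        best_combinations(records).to_csv(directory / "best_combinations.csv",
                                          index=False)
        written.append(directory / "best_combinations.csv")
    return written
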