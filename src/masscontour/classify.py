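"""Benign/malignant evaluation protocol: tables, splits, classifiers, report.

The discrimination protocol: for each subsection count C, the C-dimensional
rank-ordered feature vectors are fed to a classifier under repeated
stratified train/test splits; accuracy, sensitivity (malignant = positive)
and specificity are averaged over repetitions and then over the C sweep for
the final figure.  Three classifiers are compared: 1-nearest-neighbor, a
linear-kernel SVM, and a single-hidden-layer neural network with 10 logistic
nodes and seeded random initial weights.

A single small test split has huge variance, so the default protocol repeats
the split 100 times (seeded) and reports means; a single-split mode is
available.  Features are z-scored with training-split statistics before
every classifier, including 1-NN (standardized Euclidean distance), since
the raw feature scales differ by orders of magnitude.  The same seeded split
sequence is reused across C values and signature kinds so that method
comparisons are paired.

Classifier internals are delegated to scikit-learn; the contribution of this
module is the protocol, the metrics, and the comparison report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .exceptions import ParameterError
from .geometry import align_start, ellipse_signature, radial_signature
from .subsection import DEFAULT_C_SET, FEATURE_NAMES, sweep_subsections

__all__ = [
    "CLASSIFIER_NAMES",
    "SIGNATURE_KINDS",
    "Protocol",
    "EvalResult",
    "make_splits",
    "confusion_metrics",
    "build_feature_table",
    "evaluate",
    "compare_methods",
]

CLASSIFIER_NAMES: tuple[str, ...] = ("knn1", "linear_svm", "ann10")
SIGNATURE_KINDS: tuple[str, ...] = ("radial", "ellipse_residual")
POSITIVE_LABEL = "malignant"


@dataclass(frozen=True)
class Protocol:
    """Evaluation protocol: split sizes, repetitions and master seed.

    ``n_train`` is an absolute count if int, a fraction of the cohort if
    float.  ``repetitions=1`` replicates a literal single-split protocol.
    """

    n_train: int | float = 0.9
    repetitions: int = 100
    seed: int = 0

    def resolve_n_train(self, n_total: int) -> int:
        if isinstance(self.n_train, float) and 0 < self.n_train < 1:
            n_train = int(round(self.n_train * n_total))
        else:
            n_train = int(self.n_train)
        if not 0 < n_train < n_total:
            raise ParameterError(
                f"n_train={n_train} must satisfy 0 < n_train < n_total={n_total}"
            )
        return n_train


def make_splits(
    n_total: int,
    n_train: int,
    labels,
    repetitions: int,
    seed: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified train/test splits preserving class proportions.

    Every training split contains both classes; a test split may come out
    single-class at extreme sizes, which callers must tolerate (sensitivity
    or specificity is then undefined for that repetition).
    """
    if not 0 < n_train < n_total:
        raise ParameterError("0 < n_train < n_total required")
    y = np.asarray(labels)
    if len(y) != n_total:
        raise ParameterError("labels length must equal n_total")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("both classes must be present")
    # integer per-class training quotas proportional to class frequency
    quota = {}
    exact = counts * n_train / n_total
    base = np.floor(exact).astype(int)
    remainder = n_train - base.sum()
    order = np.argsort(-(exact - base))
    for j, cls in enumerate(classes):
        quota[cls] = int(base[j])
    for j in order[:remainder]:
        quota[classes[j]] += 1
    for cls in classes:
        if quota[cls] < 1:
            raise ParameterError(f"class {cls!r} absent from training split")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(repetitions):
        train_parts = []
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            train_parts.append(rng.choice(idx, size=quota[cls], replace=False))
        train = np.sort(np.concatenate(train_parts))
        test = np.setdiff1d(np.arange(n_total), train)
        splits.append((train, test))
    return splits


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Accuracy, sensitivity, specificity with malignant (1) positive.

    Undefined rates (no positives or no negatives in ``y_true``) are NaN and
    are excluded from averages by the caller.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    total = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / total if total else float("nan"),
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
    }


def _make_classifier(name: str, seed: int):
    if name == "knn1":
        return KNeighborsClassifier(n_neighbors=1)
    if name == "linear_svm":
        return SVC(kernel="linear", C=1.0)
    if name == "ann10":
        return MLPClassifier(
            hidden_layer_sizes=(10,),
            activation="logistic",
            max_iter=500,
            random_state=seed,
            n_iter_no_change=10,
        )
    raise ValueError(f"unknown classifier {name!r}; expected {CLASSIFIER_NAMES}")


def build_feature_table(
    contours,
    labels,
    features=FEATURE_NAMES,
    kinds=SIGNATURE_KINDS,
    C_set=DEFAULT_C_SET,
) -> pd.DataFrame:
    """Long-form labeled feature table: one row per (contour, kind, feature, C).

    Columns: id, label, kind, feature, C, values (the sorted C-vector).
    Infeasible C values for short contours are simply absent.
    """
    rows = []
    for i, (contour, label) in enumerate(zip(contours, labels)):
        cid = contour.contour_id or f"c{i:04d}"
        aligned = align_start(contour)
        for kind in kinds:
            sig = (
                radial_signature(aligned)
                if kind == "radial"
                else ellipse_signature(aligned)
            )
            for feature in features:
                sweep = sweep_subsections(sig, feature, C_set=C_set)
                for C, vec in sweep.vectors.items():
                    rows.append(
                        {
                            "id": cid,
                            "label": label,
                            "kind": kind,
                            "feature": feature,
                            "C": C,
                            "values": vec.values,
                        }
                    )
    table = pd.DataFrame(rows)
    if len(table) and table.duplicated(["id", "kind", "feature", "C"]).any():
        raise ParameterError("duplicate (id, kind, feature, C) rows")
    return table


@dataclass(frozen=True)
class EvalResult:
    """Averaged discrimination metrics for one (feature, kind, classifier)."""

    classifier: str
    feature_name: str
    kind: str
    per_C: dict[int, dict[str, float]]
    summary: dict[str, float]
    n_train: int
    n_test: int
    repetitions: int
    seed: int
    flagged_repetitions: int = 0
    skipped_repetitions: int = 0


def _zscore(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def evaluate(
    table: pd.DataFrame,
    feature: str,
    kind: str,
    classifier: str,
    protocol: Protocol,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> EvalResult:
    """Run the repeated-split protocol for one feature/kind/classifier.

    For each C present in the table: z-score with training statistics, fit,
    predict the test split, accumulate metrics; average over repetitions and
    then over C.  Pass ``splits`` to pair the evaluation with another call.
    """
    sub = table[(table["feature"] == feature) & (table["kind"] == kind)]
    if sub.empty:
        raise ParameterError(f"table has no rows for feature={feature}, kind={kind}")
    ids = sub["id"].unique()
    id_label = sub.drop_duplicates("id").set_index("id")["label"]
    y = (id_label.loc[ids].to_numpy() == POSITIVE_LABEL).astype(int)
    n_total = len(ids)
    n_train = protocol.resolve_n_train(n_total)
    if splits is None:
        splits = make_splits(
            n_total, n_train, y, protocol.repetitions, protocol.seed
        )
    per_C: dict[int, dict[str, float]] = {}
    flagged = 0
    skipped = 0
    for C, grp in sub.groupby("C"):
        grp = grp.set_index("id")
        if not set(ids).issubset(grp.index):
            warnings.warn(
                f"C={C} missing for some contours; excluded from the average",
                stacklevel=2,
            )
            continue
        grp = grp.loc[ids]
        X = np.vstack(grp["values"].to_numpy())
        reps = {"accuracy": [], "sensitivity": [], "specificity": []}
        for r, (train, test) in enumerate(splits):
            if len(np.unique(y[train])) < 2:
                warnings.warn("single-class training split skipped", stacklevel=2)
                skipped += 1
                continue
            Xtr, Xte = _zscore(X[train], X[test])
            clf = _make_classifier(classifier, seed=protocol.seed + r)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(Xtr, y[train])
                pred = clf.predict(Xte)
            m = confusion_metrics(y[test], pred)
            if np.isnan(m["sensitivity"]) or np.isnan(m["specificity"]):
                flagged += 1
            for key in reps:
                reps[key].append(m[key])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            per_C[int(C)] = {k: float(np.nanmean(v)) for k, v in reps.items()}
    summary = {
        k: float(np.mean([m[k] for m in per_C.values()]))
        for k in ("accuracy", "sensitivity", "specificity")
    }
    train0, test0 = splits[0]
    return EvalResult(
        classifier=classifier,
        feature_name=feature,
        kind=kind,
        per_C=per_C,
        summary=summary,
        n_train=len(train0),
        n_test=len(test0),
        repetitions=len(splits),
        seed=protocol.seed,
        flagged_repetitions=flagged,
        skipped_repetitions=skipped,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Feature x signature-kind x classifier comparison matrices."""

    accuracy: pd.DataFrame
    sensitivity: pd.DataFrame
    specificity: pd.DataFrame
    results: dict[tuple[str, str, str], EvalResult] = field(repr=False, default_factory=dict)


def compare_methods(
    contours,
    labels,
    protocol: Protocol,
    features=FEATURE_NAMES,
    kinds=SIGNATURE_KINDS,
    classifiers=CLASSIFIER_NAMES,
    C_set=DEFAULT_C_SET,
    table: pd.DataFrame | None = None,
) -> ComparisonReport:
    """Head-to-head comparison of signature kinds across features/classifiers.

    All cells share one seeded split sequence, so differences between the
    radial and ellipse-residual columns are paired.  Matrices are indexed by
    (feature, kind) rows and classifier columns; cells are C-averaged means.
    """
    if table is None:
        table = build_feature_table(contours, labels, features, kinds, C_set)
    y = np.asarray([1 if lb == POSITIVE_LABEL else 0 for lb in labels])
    n_total = len(y)
    n_train = protocol.resolve_n_train(n_total)
    splits = make_splits(n_total, n_train, y, protocol.repetitions, protocol.seed)
    index = pd.MultiIndex.from_product([features, kinds], names=["feature", "kind"])
    mats = {
        m: pd.DataFrame(index=index, columns=list(classifiers), dtype=float)
        for m in ("accuracy", "sensitivity", "specificity")
    }
    results = {}
    for feature in features:
        for kind in kinds:
            for clf in classifiers:
                res = evaluate(table, feature, kind, clf, protocol, splits=splits)
                results[(feature, kind, clf)] = res
                for m in mats:
                    mats[m].loc[(feature, kind), clf] = res.summary[m]
    return ComparisonReport(
        accuracy=mats["accuracy"],
        sensitivity=mats["sensitivity"],
        specificity=mats["specificity"],
        results=results,
    )
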