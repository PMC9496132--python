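"""Stratified k-fold cross-validation and the study's metric set.

Metrics: per-fold accuracy with fold-level mean and sample standard
deviation, macro-averaged true-positive rate (recall) and macro F1 from the
pooled confusion matrix, and wall-clock training time.

The cross-validation loop is leakage-safe by construction: outlier
screening statistics, projection fits and classifier fits only ever see
the training portion of each fold (a compatibility flag allows fitting the
projection on the full dataset to mimic global-reduction protocols).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from . import dimred
from .bpnn import BPNNConfig, accuracy as bpnn_accuracy, init_model, predict, train
from .features import FeatureTable, FeatureWindow, extract_features
from .preprocess import (
    PairAnomalyRule,
    drop_dead_channels,
    flag_pair_anomaly,
    remove_outliers,
    smooth_record,
)
from .synth import SampleRecord

__all__ = [
    "CVReport",
    "stratified_kfold",
    "confusion_matrix",
    "macro_tpr",
    "macro_f1",
    "cross_validate",
]


@dataclass
class CVReport:
    fold_accuracies: list[float]
    mean_accuracy: float
    std_accuracy: float
    macro_TPR: float
    macro_F1: float
    confusion: np.ndarray
    classes: list
    train_time_s: float
    n_samples: int = 0
    n_removed_outliers: int = 0


def stratified_kfold(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Disjoint test-fold index sets covering all samples; per-class counts
    across folds differ by at most one. If some class has fewer samples
    than k, stratification degenerates to a plain shuffled split (with a
    warning)."""
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    codes = np.unique(labels, return_inverse=True)[1]
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} < k={k} samples; "
            "falling back to unstratified folds"
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in splitter.split(codes)]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros(len(codes)), codes)]


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, classes: list
) -> np.ndarray:
    """Counts[i, j] = samples of class i predicted as class j."""
    index = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[index[t], index[p]] += 1
    return M


def _per_class_rates(confusion: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    confusion = np.asarray(confusion, dtype=float)
    support = confusion.sum(axis=1)
    predicted = confusion.sum(axis=0)
    tp = np.diag(confusion)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(support > 0, tp / support, np.nan)
        precision = np.where(predicted > 0, tp / predicted, 0.0)
    return recall, precision, support


def macro_tpr(confusion: np.ndarray) -> float:
    """Unweighted mean per-class recall; zero-support classes excluded."""
    recall, _, support = _per_class_rates(confusion)
    if (support == 0).any():
        warnings.warn("classes with zero support excluded from macro TPR")
    return float(np.nanmean(recall))


def macro_f1(confusion: np.ndarray) -> float:
    """Unweighted mean per-class F1; zero-support classes excluded."""
    recall, precision, support = _per_class_rates(confusion)
    if (support == 0).any():
        warnings.warn("classes with zero support excluded from macro F1")
    with np.errstate(invalid="ignore"):
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    f1 = np.where(np.isnan(recall), np.nan, f1)
    return float(np.nanmean(f1))


def _check_no_leakage(train_idx: np.ndarray, test_idx: np.ndarray) -> None:
    if np.intersect1d(train_idx, test_idx).size:
        raise RuntimeError(
            "leakage-guard violation: training and test folds overlap"
        )


def _fit_reduction(method: str, k, X: np.ndarray, labels: np.ndarray):
    method = method.lower()
    if method == "none":
        return None
    if method == "pca":
        if k is None:
            full = dimred.fit_pca(X, min(X.shape[0] - 1, X.shape[1]))
            cum = np.cumsum(full.explained)
            k = int(np.searchsorted(cum, 0.95) + 1)
        return dimred.fit_pca(X, k)
    if method == "lda":
        n_classes = len(set(labels.tolist()))
        k = min(k or n_classes - 1, n_classes - 1)
        return dimred.fit_lda(X, labels, k)
    if method == "fa":
        return dimred.fit_fa(X, k or 3)
    raise ValueError(f"unknown reduction method {method!r}")


def _fit_classifier(model_section, X: np.ndarray, labels: np.ndarray, classes: list):
    """Fit the configured classifier; returns a predict(X)->labels callable."""
    kind = model_section.kind.lower()
    if kind == "bpnn":
        cfg = BPNNConfig(
            input_dim=X.shape[1],
            hidden_sizes=tuple(model_section.hidden_sizes),
            n_classes=len(classes),
            activation=model_section.activation,
            learning_rate=model_section.learning_rate,
            epochs=model_section.epochs,
            seed=model_section.seed,
        )
        model = train(init_model(cfg), X, labels)
        return lambda Xt: predict(model, Xt)
    codes = {c: i for i, c in enumerate(classes)}
    inv = {i: c for c, i in codes.items()}
    y = np.array([codes[l] for l in labels])
    if kind == "knn":
        clf = KNeighborsClassifier(n_neighbors=model_section.knn_neighbors)
    elif kind == "svm":
        clf = SVC(kernel="rbf", C=model_section.svm_c, gamma="scale")
    elif kind == "rf":
        clf = RandomForestClassifier(
            n_estimators=model_section.rf_trees, random_state=model_section.seed
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    clf.fit(X, y)
    return lambda Xt: np.array([inv[i] for i in clf.predict(Xt)], dtype=object)


def prepare_features(dataset: list[SampleRecord], pipeline) -> FeatureTable:
    """Stateless per-record stages: smoothing, pair-anomaly removal,
    dead-channel exclusion, descriptor extraction."""
    pp = pipeline.preprocess
    records = [smooth_record(r, pp.smooth_k) for r in dataset]
    if pp.apply_pair_rule:
        rule = pp.pair_rule or PairAnomalyRule()
        records = [r for r in records if not flag_pair_anomaly(r, rule)]
    if not records:
        raise ValueError("pair-anomaly rule removed every record")
    records, _ = drop_dead_channels(records, pp.dead_epsilon)
    feats = pipeline.features
    return extract_features(
        records,
        window=feats.window or FeatureWindow(),
        stable_fraction=feats.stable_fraction,
    )


def cross_validate(
    pipeline,
    dataset: list[SampleRecord] | FeatureTable,
    k: int | None = None,
    seed: int | None = None,
) -> CVReport:
    """Stratified k-fold evaluation of the configured pipeline.

    `dataset` may be raw sample records (the per-record stages run first)
    or an already-extracted :class:`FeatureTable`. Within each fold the
    outlier screen, the projection and the classifier are fit on the
    training portion only; the held-out fold is only ever transformed.
    """
    ev = pipeline.evaluation
    k = k if k is not None else ev.k
    seed = seed if seed is not None else ev.seed
    if isinstance(dataset, FeatureTable):
        table = dataset
    else:
        table = prepare_features(dataset, pipeline)
    X, labels = table.X, table.labels
    classes = sorted(set(labels.tolist()))
    folds = stratified_kfold(labels, k=k, seed=seed)
    all_idx = np.arange(len(X))
    red = pipeline.reduction
    global_model = None
    if red.method.lower() != "none" and red.global_fit:
        global_model = _fit_reduction(red.method, red.k, X, labels)
    fold_accs: list[float] = []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    n_removed_total = 0
    t0 = time.perf_counter()
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        _check_no_leakage(train_idx, test_idx)
        X_tr, y_tr = X[train_idx], labels[train_idx]
        X_te, y_te = X[test_idx], labels[test_idx]
        if pipeline.preprocess.alpha is not None:
            X_tr, y_tr, rep = remove_outliers(
                X_tr, y_tr, alpha=pipeline.preprocess.alpha
            )
            n_removed_total += len(rep.removed_indices)
        model_section = pipeline.model
        if (
            getattr(pipeline, "optimizer", None) is not None
            and pipeline.optimizer.enabled
            and pipeline.optimizer.per_fold
        ):
            from .optim import optimize_bpnn_architecture  # lazy: avoid cycle

            proj_tmp = (
                _fit_reduction(red.method, red.k, X_tr, y_tr)
                if global_model is None and red.method.lower() != "none"
                else global_model
            )
            X_opt = dimred.transform(proj_tmp, X_tr) if proj_tmp else X_tr
            incumbent = model_section.hidden_sizes
            template = BPNNConfig(
                input_dim=X_opt.shape[1],
                n_classes=len(set(y_tr.tolist())),
                activation=model_section.activation,
                learning_rate=model_section.learning_rate,
                epochs=model_section.epochs,
                seed=model_section.seed,
            )
            best_sizes, _ = optimize_bpnn_architecture(
                X_opt,
                y_tr,
                algorithm=pipeline.optimizer.algorithm,
                node_bounds=pipeline.optimizer.node_bounds,
                swarm=pipeline.optimizer.swarm,
                bpnn_template=template,
                initial_guess=(
                    incumbent
                    if len(incumbent) == len(pipeline.optimizer.node_bounds)
                    else None
                ),
            )
            model_section = model_section.with_(hidden_sizes=best_sizes)
        if red.method.lower() != "none":
            proj = global_model or _fit_reduction(red.method, red.k, X_tr, y_tr)
            Z_tr = dimred.transform(proj, X_tr)
            Z_te = dimred.transform(proj, X_te)
        else:
            Z_tr, Z_te = X_tr, X_te
        predict_fn = _fit_classifier(model_section, Z_tr, y_tr, classes)
        y_pred = predict_fn(Z_te)
        fold_accs.append(float(np.mean(y_pred == y_te)))
        confusion += confusion_matrix(y_te, y_pred, classes)
    elapsed = time.perf_counter() - t0
    accs = np.array(fold_accs)
    return CVReport(
        fold_accuracies=fold_accs,
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        macro_TPR=macro_tpr(confusion),
        macro_F1=macro_f1(confusion),
        confusion=confusion,
        classes=classes,
        train_time_s=elapsed,
        n_samples=len(X),
        n_removed_outliers=n_removed_total,
    )
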