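"""RBF-SVM treatment-response classification on the selected edges.

Fivefold cross-validated grid search over (cost, gamma) maximizing mean
held-out AUC, class weights set from the group-size ratio to offset the
responder/nonresponder imbalance, ROC analysis with the Youden-J optimal
cutoff, and aggregation of a patient's epoch calls into one response label
by majority vote (responder only when strictly more than half the epochs
vote responder; exact ties are called nonresponder).

Features are z-scored per edge using training-data statistics only;
zero-variance columns are passed through unscaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from vnsnet.preprocessing import NONRESPONDER, RESPONDER

POSITIVE = RESPONDER

DEFAULT_COSTS = tuple(2.0**k for k in range(-5, 16, 2))
DEFAULT_GAMMAS = tuple(2.0**k for k in range(-15, 4, 2))


@dataclass
class GridSpec:
    costs: tuple = DEFAULT_COSTS
    gammas: tuple = DEFAULT_GAMMAS
    n_folds: int = 5
    fold_unit: str = "epoch"  # epoch | patient
    seed: int = 0

    def __post_init__(self):
        if not self.costs or not self.gammas:
            raise ValueError("grids must be nonempty")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.fold_unit not in ("epoch", "patient"):
            raise ValueError("fold_unit must be 'epoch' or 'patient'")


@dataclass
class TrainedClassifier:
    model: SVC
    cost: float
    gamma: float
    class_weights: dict
    feature_names: list[str]
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    cutoff: float = 0.0
    standardized: bool = True


@dataclass
class EvaluationReport:
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    cutoff: float
    confusion: dict = field(default_factory=dict)
    roc: pd.DataFrame | None = None
    per_fold: list[dict] = field(default_factory=list)


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "OUS":
        return (labels == POSITIVE).astype(int)
    return labels.astype(int)


def _fit_scaler(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def class_weight_ratio(y: np.ndarray) -> dict:
    """Weight of class c = n_other / n_c (minority class weighted > 1)."""
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    return {1: n0 / n1, 0: n1 / n0}


def cv_folds(labels, patient_ids=None, n_folds: int = 5, fold_unit: str = "epoch", seed=0):
    """Fold index per row: label-stratified for epoch unit, grouped so no
    patient spans folds for patient unit. Deterministic under seed."""
    y = _as_binary(labels)
    folds = np.empty(len(y), dtype=int)
    if fold_unit == "epoch":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for k, (_, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
            folds[test_idx] = k
        return folds
    if patient_ids is None:
        raise ValueError("patient_ids required for fold_unit='patient'")
    patient_ids = np.asarray(patient_ids)
    uniq = np.unique(patient_ids)
    patient_y = np.array([y[patient_ids == u][0] for u in uniq])
    if min(np.bincount(patient_y, minlength=2)) < n_folds:
        raise ValueError("too few patients per class for the requested folds")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    patient_fold = np.empty(len(uniq), dtype=int)
    for k, (_, test_idx) in enumerate(splitter.split(np.zeros(len(uniq)), patient_y)):
        patient_fold[test_idx] = k
    lookup = dict(zip(uniq, patient_fold))
    return np.array([lookup[p] for p in patient_ids])


def train_svm(
    X: np.ndarray,
    labels,
    cost: float,
    gamma: float,
    feature_names=None,
    standardize: bool = True,
) -> TrainedClassifier:
    """Fit the class-weighted RBF SVM on (optionally) z-scored features."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if standardize:
        mean, sd = _fit_scaler(X)
    else:
        mean, sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
    weights = class_weight_ratio(y)
    model = SVC(kernel="rbf", C=cost, gamma=gamma, class_weight=weights)
    model.fit((X - mean) / sd, y)
    return TrainedClassifier(
        model=model,
        cost=float(cost),
        gamma=float(gamma),
        class_weights=weights,
        feature_names=list(feature_names) if feature_names is not None else [],
        scale_mean=mean,
        scale_sd=sd,
        standardized=standardize,
    )


def decision_scores(clf: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    return clf.model.decision_function((np.asarray(X, float) - clf.scale_mean) / clf.scale_sd)


def roc_curve_auc(scores, labels):
    """ROC points, trapezoidal AUC and the Youden-J optimal cutoff.

    AUC equals the Mann-Whitney U / (n+ n-) probability under the midrank
    tie convention.
    """
    y = _as_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thresholds = metrics.roc_curve(y, scores)
    auc = float(metrics.roc_auc_score(y, scores))
    youden = tpr - fpr
    best = int(np.argmax(youden))
    cutoff = float(thresholds[best])
    if np.isinf(cutoff):  # sklearn's sentinel above the max score
        cutoff = float(scores.max() + 1.0)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return roc, auc, cutoff


def grid_search_svm(X, labels, spec: GridSpec, patient_ids=None):
    """Exhaustive (cost, gamma) search maximizing mean held-out-fold AUC.

    Standardization statistics come from the four training folds only.
    Ties prefer the smallest cost, then the smallest gamma.
    """
    X = np.asarray(X, dtype=float)
    y = _as_binary(labels)
    folds = cv_folds(y, patient_ids, spec.n_folds, spec.fold_unit, spec.seed)
    results = []
    best = None
    for cost in sorted(spec.costs):
        for gamma in sorted(spec.gammas):
            aucs = []
            for k in range(spec.n_folds):
                train, test = folds != k, folds == k
                if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                    raise ValueError(f"fold {k} is single-class; reseed or regroup")
                clf = train_svm(X[train], y[train], cost, gamma)
                scores = decision_scores(clf, X[test])
                aucs.append(metrics.roc_auc_score(y[test], scores))
            mean_auc = float(np.mean(aucs))
            results.append(
                {"cost": cost, "gamma": gamma, "mean_auc": mean_auc, "fold_aucs": aucs}
            )
            if best is None or mean_auc > best["mean_auc"]:
                best = results[-1]
    return best["cost"], best["gamma"], pd.DataFrame(results)


def cross_val_scores(X, labels, cost: float, gamma: float, folds, standardize=True):
    """Out-of-fold decision scores at fixed (cost, gamma).

    Each epoch is scored by the model trained on the other folds, so the
    score distribution matches what unseen data would see; the Youden
    cutoff is calibrated on these rather than on resubstitution scores.
    """
    X = np.asarray(X, dtype=float)
    y = _as_binary(labels)
    folds = np.asarray(folds)
    scores = np.empty(len(y))
    for k in np.unique(folds):
        train, test = folds != k, folds == k
        clf = train_svm(X[train], y[train], cost, gamma, standardize=standardize)
        scores[test] = decision_scores(clf, X[test])
    return scores


def evaluate_epochs(
    clf: TrainedClassifier, X, labels, cutoff: float | None = None
) -> EvaluationReport:
    """Epoch-level AUC / sensitivity / specificity / accuracy.

    Responder is the positive class; epochs are called at ``cutoff``
    (default: the classifier's stored training-derived cutoff).
    """
    y = _as_binary(labels)
    scores = decision_scores(clf, X)
    roc, auc, _ = roc_curve_auc(scores, y)
    if cutoff is None:
        cutoff = clf.cutoff
    pred = (scores >= cutoff).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    return EvaluationReport(
        auc=auc,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        accuracy=(tp + tn) / len(y),
        cutoff=float(cutoff),
        confusion={"TP": tp, "FN": fn, "TN": tn, "FP": fp},
        roc=roc,
    )


def patient_vote(pred_labels, patient_ids) -> dict[str, str]:
    """Majority vote over a patient's epoch calls.

    Responder only when strictly more than half the epochs are called
    responder; an exact tie is called nonresponder (conservative).
    """
    pred = _as_binary(pred_labels)
    patient_ids = np.asarray(patient_ids)
    votes = {}
    for pid in np.unique(patient_ids):
        mask = patient_ids == pid
        votes[str(pid)] = (
            RESPONDER if pred[mask].sum() * 2 > mask.sum() else NONRESPONDER
        )
    return votes


def evaluate_patients(pred_labels, patient_ids, true_labels) -> dict:
    """Patient-level confusion counts from majority voting."""
    votes = patient_vote(pred_labels, patient_ids)
    patient_ids = np.asarray(patient_ids)
    truth = {
        str(pid): np.asarray(true_labels)[patient_ids == pid][0]
        for pid in np.unique(patient_ids)
    }
    counts = {"TP": 0, "FN": 0, "TN": 0, "FP": 0}
    for pid, vote in votes.items():
        real = truth[pid]
        if real == RESPONDER:
            counts["TP" if vote == RESPONDER else "FN"] += 1
        else:
            counts["TN" if vote == NONRESPONDER else "FP"] += 1
    n = len(votes)
    counts["accuracy"] = (counts["TP"] + counts["TN"]) / n if n else float("nan")
    counts["votes"] = votes
    return counts
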