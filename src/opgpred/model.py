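"""Progression classification: SVM + forward selection under paired leave-two-out CV.

The classifier is a linear-kernel support vector machine with features
z-scored on the training split only. Feature subsets are chosen by
greedy sequential forward selection: at each step the candidate feature
maximizing inner 5-fold stratified CV accuracy joins the model, stopping
at the first step with no strict improvement (ties break toward the
lower column index).

Cross-validation enumerates every (case, control) pair: each fold trains
on all subjects except that pair and predicts the held-out pair, giving
n_cases * n_controls folds. A subject's final prediction is the majority
vote of its per-fold predictions (mean decision score breaks ties) and
the per-subject decision score is the mean across folds; the confusion
table, accuracy/sensitivity/specificity, ROC/AUC with bootstrap CI, and
the univariate per-feature AUC ranking are reported together.

AUC is computed rank-based (ties counted one half), which equals the
Mann-Whitney U statistic divided by n1*n2 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InsufficientDataError
from .features import FeatureTable

__all__ = [
    "POSITIVE",
    "ConfusionCounts",
    "Metrics",
    "ROCResult",
    "ModelReport",
    "leave_two_out_folds",
    "fit_predict_svm",
    "sequential_forward_selection",
    "compute_metrics",
    "rank_auc",
    "roc_analysis",
    "rank_features_by_auc",
    "cross_validate",
]

log = logging.getLogger(__name__)

POSITIVE = "case"  # progression is the positive class throughout


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        t = np.asarray(y_true) == POSITIVE
        p = np.asarray(y_pred) == POSITIVE
        return cls(
            tp=int((t & p).sum()),
            tn=int((~t & ~p).sum()),
            fp=int((~t & p).sum()),
            fn=int((t & ~p).sum()),
        )


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray  # per threshold
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    optimal_cutoff: float
    optimal_point: tuple[float, float]  # (1 - specificity, sensitivity)


@dataclass
class ModelReport:
    scheme: str
    selected_features: list[str]
    fold_predictions: pd.DataFrame  # one row per (fold, test subject)
    subject_predictions: pd.DataFrame  # aggregated per subject
    confusion: ConfusionCounts
    metrics: Metrics
    roc: ROCResult
    feature_ranking: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "selected_features": self.selected_features,
            "confusion": vars(self.confusion) | {},
            "accuracy": self.metrics.accuracy,
            "sensitivity": self.metrics.sensitivity,
            "specificity": self.metrics.specificity,
            "undefined_metrics": list(self.metrics.undefined),
            "auc": self.roc.auc,
            "auc_ci95": list(self.roc.auc_ci),
            "optimal_cutoff": self.roc.optimal_cutoff,
            "optimal_point": list(self.roc.optimal_point),
            "subject_predictions": self.subject_predictions.reset_index().to_dict("records"),
            "feature_ranking_top10": self.feature_ranking.head(10)
            .reset_index()
            .to_dict("records"),
            "metadata": self.metadata,
        }


# ---------------------------------------------------------------------------
# folds


def leave_two_out_folds(labels: Sequence[str]) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """One fold per (case, control) pair of subject indices.

    Each fold's training set is every subject except the pair, so there
    are n_cases * n_controls folds and every subject is tested at least
    once. Requires at least 2 subjects of each class.
    """
    y = np.asarray(labels)
    cases = np.flatnonzero(y == POSITIVE)
    controls = np.flatnonzero(y != POSITIVE)
    if len(cases) < 2 or len(controls) < 2:
        raise InsufficientDataError(
            f"need >= 2 of each class, got {len(cases)} cases / {len(controls)} controls"
        )
    all_idx = np.arange(len(y))
    folds = []
    for ci in cases:
        for ki in controls:
            train = all_idx[(all_idx != ci) & (all_idx != ki)]
            folds.append((train, (int(ci), int(ki))))
    return folds


# ---------------------------------------------------------------------------
# SVM


def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def fit_predict_svm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    C: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear SVM predictions and decision scores for test rows.

    Standardization parameters come from the training rows only, so no
    test-set statistics leak into the fit. Decision scores are oriented
    so positive means the progression class.
    """
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("training labels contain a single class")
    mu, sd = _zscore_fit(np.asarray(X_train, dtype=float))
    Xtr = (X_train - mu) / sd
    Xte = (np.asarray(X_test, dtype=float) - mu) / sd
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xtr, (y == POSITIVE).astype(int))
    scores = clf.decision_function(Xte)
    preds = np.where(scores > 0, POSITIVE, "control")
    return preds, scores


# ---------------------------------------------------------------------------
# sequential forward selection


def _inner_cv_accuracy(
    X: np.ndarray, y01: np.ndarray, cols: list[int], splits, C: float
) -> float:
    correct = 0
    total = 0
    Xc = X[:, cols]
    for tr, te in splits:
        mu, sd = _zscore_fit(Xc[tr])
        clf = SVC(kernel="linear", C=C)
        clf.fit((Xc[tr] - mu) / sd, y01[tr])
        pred = clf.predict((Xc[te] - mu) / sd)
        correct += int((pred == y01[te]).sum())
        total += len(te)
    return correct / total


def sequential_forward_selection(
    X: np.ndarray,
    y: np.ndarray,
    max_features: int | None = None,
    inner_folds: int = 5,
    C: float = 1.0,
    seed: int = 0,
    prescreen: int | None = None,
) -> tuple[list[int], list[float]]:
    """Greedy forward selection by inner-CV accuracy of the SVM.

    Starting from the majority-class baseline accuracy, the candidate
    feature with the highest inner stratified-CV accuracy is added at
    each step; selection stops at the first step with no strict
    improvement or at ``max_features``. Ties break toward the lower
    column index. Returns the selected column indices (in order of
    addition) and the accuracy path.

    ``prescreen`` optionally restricts the candidate pool to the top-N
    features by univariate AUC on the given (training) rows before the
    greedy loop — a standard filter-then-wrapper economy for tables
    with hundreds of columns; it sees only the rows it is given, so it
    leaks nothing from held-out data.

    When the training set is too small for a 2-fold stratified split,
    training-set accuracy is used as the selection criterion instead.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InsufficientDataError("forward selection needs both classes")
    y01 = (y == POSITIVE).astype(int)
    n_splits = min(inner_folds, int(counts.min()))
    if n_splits >= 2:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y01))
    else:  # degenerate: resubstitution accuracy
        idx = np.arange(len(y))
        splits = [(idx, idx)]
    if max_features is None:
        max_features = X.shape[1]
    best_acc = counts.max() / counts.sum()  # majority-class baseline
    selected: list[int] = []
    path: list[float] = []
    remaining = list(range(X.shape[1]))
    if prescreen is not None and prescreen < len(remaining):
        aucs = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            col = X[:, j]
            if np.ptp(col) == 0:
                aucs[j] = 0.5
            else:
                a = rank_auc(col, y)
                aucs[j] = max(a, 1.0 - a)
        # stable sort keeps the lower-index tie-break convention
        order = np.argsort(-aucs, kind="stable")[:prescreen]
        remaining = sorted(int(j) for j in order)
    while remaining and len(selected) < max_features:
        accs = [
            _inner_cv_accuracy(X, y01, selected + [f], splits, C) for f in remaining
        ]
        j = int(np.argmax(accs))  # first max -> lowest column index wins ties
        if accs[j] <= best_acc + 1e-12:
            break
        best_acc = accs[j]
        selected.append(remaining.pop(j))
        path.append(best_acc)
    return selected, path


# ---------------------------------------------------------------------------
# metrics and ROC


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity with zero-denominator flags."""
    if counts.total == 0:
        raise InsufficientDataError("no predictions to score")
    undefined = []
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fn > 0:
        sensitivity = counts.tp / (counts.tp + counts.fn)
    else:
        sensitivity = float("nan")
        undefined.append("sensitivity")
    if counts.tn + counts.fp > 0:
        specificity = counts.tn / (counts.tn + counts.fp)
    else:
        specificity = float("nan")
        undefined.append("specificity")
    return Metrics(accuracy, sensitivity, specificity, tuple(undefined))


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    y = np.asarray(labels) == POSITIVE
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise InsufficientDataError("AUC needs both classes")
    ranks = stats.rankdata(np.asarray(scores, dtype=float))
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_analysis(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """ROC curve, rank-based AUC, bootstrap CI and closest-to-(0,1) cutoff.

    The 95% CI is a stratified bootstrap percentile interval (resampling
    cases and controls separately, ``n_boot`` resamples, seeded). The
    optimal cutoff is the threshold whose ROC point minimizes the
    Euclidean distance to the ideal corner (0, 1).
    """
    y = np.asarray(labels) == POSITIVE
    s = np.asarray(scores, dtype=float)
    auc = rank_auc(s, labels)
    fpr, tpr, thresholds = roc_curve(y.astype(int), s)
    dist = np.sqrt(fpr**2 + (1.0 - tpr) ** 2)
    j = int(np.argmin(dist))
    rng = np.random.default_rng(seed)
    pos, neg = s[y], s[~y]
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bs = np.concatenate(
            [
                rng.choice(pos, size=len(pos), replace=True),
                rng.choice(neg, size=len(neg), replace=True),
            ]
        )
        bl = np.concatenate([np.full(len(pos), POSITIVE), np.full(len(neg), "control")])
        boot[b] = rank_auc(bs, bl)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        auc_ci=(float(lo), float(hi)),
        optimal_cutoff=float(thresholds[j]),
        optimal_point=(float(fpr[j]), float(tpr[j])),
    )


def rank_features_by_auc(table: FeatureTable | pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    """Univariate AUC (oriented to >= 0.5) and two-sided Mann-Whitney p per feature.

    Constant features record AUC 0.5 and p = 1. Sorted descending by
    oriented AUC; ties keep column order.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    y = np.asarray(labels) == POSITIVE
    if y.all() or not y.any():
        raise InsufficientDataError("feature ranking needs both classes")
    rows = []
    for col in df.columns:
        v = df[col].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            rows.append((col, 0.5, 0.5, 1.0))
            continue
        a = rank_auc(v, labels)
        res = stats.mannwhitneyu(v[y], v[~y], alternative="two-sided", method="asymptotic")
        rows.append((col, max(a, 1.0 - a), a, float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["feature", "auc", "auc_raw", "p_value"])
    out = out.sort_values("auc", ascending=False, kind="stable").set_index("feature")
    return out


# ---------------------------------------------------------------------------
# leave-two-out driver


def _majority(preds: Sequence[str], mean_score: float) -> str:
    votes = int(sum(p == POSITIVE for p in preds))
    if 2 * votes > len(preds):
        return POSITIVE
    if 2 * votes < len(preds):
        return "control"
    return POSITIVE if mean_score > 0 else "control"


def cross_validate(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    seed: int = 0,
    C: float = 1.0,
    max_features: int | None = 10,
    inner_folds: int = 5,
    prescreen: int | None = None,
) -> ModelReport:
    """Paired leave-two-out cross-validation of the full selection + SVM pipeline.

    Within each fold, forward selection and the SVM fit see only the
    fold's training rows. Subjects contributing several rows (static
    scheme) are predicted by majority vote over their row predictions.
    """
    if labels is None:
        labels = table.labels
    if labels is None:
        raise InsufficientDataError("labels are required")
    X = table.data.to_numpy(dtype=float)
    row_labels = np.asarray(labels)
    row_subjects = np.asarray(table.subject_ids)
    subj_ids = list(dict.fromkeys(table.subject_ids))  # first-appearance order
    subj_label = {
        sid: row_labels[row_subjects == sid][0] for sid in subj_ids
    }
    subj_y = np.asarray([subj_label[sid] for sid in subj_ids])
    folds = leave_two_out_folds(subj_y)

    fold_rows = []
    per_subject_preds: dict[str, list[str]] = {sid: [] for sid in subj_ids}
    per_subject_scores: dict[str, list[float]] = {sid: [] for sid in subj_ids}
    for f, (train_subj_idx, (ci, ki)) in enumerate(folds):
        train_sids = {subj_ids[t] for t in train_subj_idx}
        test_sids = [subj_ids[ci], subj_ids[ki]]
        tr = np.isin(row_subjects, list(train_sids))
        fold_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(f,)).generate_state(1)[0] % (2**31))
        selected, _ = sequential_forward_selection(
            X[tr], row_labels[tr], max_features=max_features,
            inner_folds=inner_folds, C=C, seed=fold_seed, prescreen=prescreen,
        )
        for sid in test_sids:
            te = row_subjects == sid
            if selected:
                preds, scores = fit_predict_svm(
                    X[tr][:, selected], row_labels[tr], X[te][:, selected], C=C
                )
            else:  # nothing discriminative: fall back to training majority
                vals, cnts = np.unique(row_labels[tr], return_counts=True)
                maj = vals[np.argmax(cnts)]
                preds = np.full(int(te.sum()), maj)
                scores = np.zeros(int(te.sum()))
            mean_score = float(np.mean(scores))
            pred = _majority(list(preds), mean_score)
            per_subject_preds[sid].append(pred)
            per_subject_scores[sid].append(mean_score)
            fold_rows.append(
                {
                    "fold": f,
                    "subject_id": sid,
                    "true": subj_label[sid],
                    "pred": pred,
                    "score": mean_score,
                    "n_selected": len(selected),
                }
            )
    fold_df = pd.DataFrame(fold_rows)

    agg_rows = []
    for sid in subj_ids:
        mean_score = float(np.mean(per_subject_scores[sid]))
        pred = _majority(per_subject_preds[sid], mean_score)
        agg_rows.append(
            {"subject_id": sid, "true": subj_label[sid], "pred": pred, "score": mean_score}
        )
    agg = pd.DataFrame(agg_rows).set_index("subject_id")

    counts = ConfusionCounts.from_predictions(agg["true"].to_numpy(), agg["pred"].to_numpy())
    metrics = compute_metrics(counts)
    roc = roc_analysis(agg["score"].to_numpy(), agg["true"].to_numpy(), seed=seed)
    ranking = rank_features_by_auc(table, row_labels)

    final_selected, _ = sequential_forward_selection(
        X, row_labels, max_features=max_features, inner_folds=inner_folds, C=C,
        seed=seed, prescreen=prescreen,
    )
    report = ModelReport(
        scheme=table.scheme,
        selected_features=[table.columns[j] for j in final_selected],
        fold_predictions=fold_df,
        subject_predictions=agg,
        confusion=counts,
        metrics=metrics,
        roc=roc,
        feature_ranking=ranking,
        metadata={
            "n_folds": len(folds),
            "svm": {"kernel": "linear", "C": C},
            "seed": seed,
            "subject_aggregation": "majority vote over fold/row predictions",
            "specificity_definition": "TN/(TN+FP) (standard form)",
        },
    )
    return report
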