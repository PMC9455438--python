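"""Model assessment: leave-one-out cross-validation, confusion-matrix
metrics, R²/Q², and one-vs-rest ROC curves with AUC significance.

Conventions
-----------
* LOO-CV refits centring/scaling and the PLS-DA model on every fold of
  n - 1 samples; Savitzky-Golay preprocessing is strictly per-sample and
  therefore applied once, outside the loop.
* R² = 1 - ||Y - Yhat_train||² / ||Y - Ybar||² on the dummy response
  (goodness of fit); Q² = 1 - PRESS/TSS with PRESS accumulated over the
  held-out predictions (goodness of prediction).  R² grows with model
  complexity; Q² peaks at the true signal rank and then degrades.
* Per-class ROC curves are one-vs-rest on the held-out predicted dummy
  scores; AUC is the trapezoidal area, which equals the Mann-Whitney
  statistic U/(n+ n-) with ties counted 1/2.  AUC significance is the
  two-sided Wilcoxon rank-sum (Mann-Whitney) test of positive vs negative
  scores, normal approximation with tie and continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .plsda_core import PLSDAModel, encode_dummy, fit_plsda
from .spectra_io import SpectraSet

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "ROCCurve",
    "CVReport",
    "ComponentScan",
    "confusion_matrix",
    "confusion_metrics",
    "roc_auc",
    "r2_explained",
    "q2_press",
    "loo_cv",
    "component_scan",
]


@dataclass
class ConfusionMatrix:
    """k x k count matrix; rows are true classes, columns assigned classes."""

    class_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.class_labels, columns=self.class_labels
        )


def confusion_matrix(
    true_labels, assigned_labels, class_labels: list[str] | None = None
) -> ConfusionMatrix:
    true_labels = [str(l) for l in true_labels]
    assigned_labels = [str(l) for l in assigned_labels]
    if len(true_labels) != len(assigned_labels):
        raise ValueError("label lists differ in length")
    if class_labels is None:
        class_labels = sorted(set(true_labels) | set(assigned_labels))
    index = {lab: j for j, lab in enumerate(class_labels)}
    counts = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    for t, a in zip(true_labels, assigned_labels):
        counts[index[t], index[a]] += 1
    return ConfusionMatrix(class_labels=list(class_labels), counts=counts)


@dataclass
class ClassMetrics:
    """Per-class precision/sensitivity/specificity plus overall summaries.

    Undefined ratios (0/0, e.g. precision of a class never assigned) are
    NaN in ``per_class`` and listed in ``undefined``; macro averages are
    taken over the defined entries only.
    """

    per_class: pd.DataFrame  # index = class labels; columns = the 3 metrics
    accuracy: float
    macro: dict[str, float]
    undefined: list[tuple[str, str]] = field(default_factory=list)


def confusion_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Precision, sensitivity and specificity per class from raw counts.

    For class c: TP = counts[c, c]; FN = (row c) - TP; FP = (column c) - TP;
    TN = total - TP - FN - FP; precision = TP/(TP+FP),
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP);
    overall accuracy = trace/total.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    undefined: list[tuple[str, str]] = []
    counts = cm.counts
    for j, label in enumerate(cm.class_labels):
        tp = counts[j, j]
        fn = counts[j, :].sum() - tp
        fp = counts[:, j].sum() - tp
        tn = total - tp - fn - fp
        vals = {}
        for name, num, den in (
            ("precision", tp, tp + fp),
            ("sensitivity", tp, tp + fn),
            ("specificity", tn, tn + fp),
        ):
            if den == 0:
                vals[name] = np.nan
                undefined.append((label, name))
            else:
                vals[name] = num / den
        rows[label] = vals
    per_class = pd.DataFrame.from_dict(rows, orient="index").loc[cm.class_labels]
    accuracy = float(np.trace(counts)) / total
    macro = {col: float(per_class[col].mean(skipna=True)) for col in per_class.columns}
    return ClassMetrics(
        per_class=per_class, accuracy=accuracy, macro=macro, undefined=undefined
    )


@dataclass
class ROCCurve:
    """One-vs-rest ROC curve with trapezoidal AUC and rank-sum p-value."""

    class_label: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    p_value: float


def roc_auc(scores, positives, class_label: str = "") -> ROCCurve:
    """ROC curve from sweeping every distinct score threshold.

    A sample is called positive when its score >= threshold.  The AUC by
    trapezoid over the resulting staircase equals the probability that a
    random positive outscores a random negative, ties counted half — the
    Mann-Whitney U statistic scaled by n+ n-; the implementation asserts
    that identity internally.
    """
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    if scores.shape != positives.shape or scores.ndim != 1:
        raise ValueError("scores and positives must be matching 1-D arrays")
    n_pos = int(positives.sum())
    n_neg = int(scores.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative sample")

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = positives[order]
    tp_cum = np.cumsum(sorted_pos)
    fp_cum = np.cumsum(~sorted_pos)
    # one operating point per distinct score value (the last index of each tie
    # group), plus the (0, 0) point at threshold +inf
    last_of_group = np.flatnonzero(np.diff(sorted_scores, append=-np.inf))
    thresholds = np.concatenate(([np.inf], sorted_scores[last_of_group]))
    tpr = np.concatenate(([0.0], tp_cum[last_of_group] / n_pos))
    fpr = np.concatenate(([0.0], fp_cum[last_of_group] / n_neg))
    auc = float(np.trapezoid(tpr, fpr))

    # internal cross-check against the rank-based (Mann-Whitney) estimator
    ranks = stats.rankdata(scores)
    u_stat = ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0
    auc_rank = u_stat / (n_pos * n_neg)
    if not np.isclose(auc, auc_rank, atol=1e-12):
        raise AssertionError(
            f"trapezoid AUC {auc} != rank-based AUC {auc_rank}"
        )

    pos_scores, neg_scores = scores[positives], scores[~positives]
    if np.ptp(scores) == 0:
        p_value = 1.0  # complete ties carry no ranking information
    else:
        p_value = float(
            stats.mannwhitneyu(
                pos_scores, neg_scores, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    return ROCCurve(
        class_label=class_label,
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        p_value=p_value,
    )


@dataclass
class CVReport:
    """Everything the leave-one-out assessment produces for one dataset."""

    A: int
    confusion: ConfusionMatrix
    metrics: ClassMetrics
    r2: float
    q2: float
    roc: list[ROCCurve]
    held_out_scores: np.ndarray  # n x k predicted dummy responses
    settings: dict = field(default_factory=dict)
    fold_warnings: list[str] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.metrics.accuracy

    def auc_by_class(self) -> dict[str, float]:
        return {r.class_label: r.auc for r in self.roc}

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "accuracy": self.accuracy,
            "r2": self.r2,
            "q2": self.q2,
            "confusion": {
                "class_labels": self.confusion.class_labels,
                "counts": self.confusion.counts.tolist(),
            },
            "per_class_metrics": {
                lab: {
                    m: (None if np.isnan(v) else float(v))
                    for m, v in row.items()
                }
                for lab, row in self.metrics.per_class.iterrows()
            },
            "macro": self.metrics.macro,
            "undefined_metrics": [list(t) for t in self.metrics.undefined],
            "auc": {r.class_label: r.auc for r in self.roc},
            "auc_p_value": {r.class_label: r.p_value for r in self.roc},
            "settings": self.settings,
            "fold_warnings": self.fold_warnings,
        }


def r2_explained(s: SpectraSet, model: PLSDAModel) -> float:
    """Explained variation of the dummy response by the training fit."""
    coding = encode_dummy(s.origins, class_labels=model.class_labels)
    yhat = model.predict_response(s.intensities)
    resid = np.linalg.norm(coding.Y - yhat) ** 2
    tss = np.linalg.norm(coding.Y - coding.Y.mean(axis=0)) ** 2
    if tss == 0:
        raise ValueError("degenerate response: zero total sum of squares")
    return 1.0 - resid / tss


def _loo_held_out_scores(
    s: SpectraSet,
    A: int,
    autoscale: bool,
    class_labels: list[str],
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[str]]:
    """Predicted dummy response of each sample from the model trained
    without it.  Returns (n x k scores, fold warnings)."""
    n = s.n
    scores = np.zeros((n, len(class_labels)))
    fold_warnings: list[str] = []
    origins = s.origins
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        train = s.subset(keep)
        if len(set(origins[keep])) < len(class_labels):
            fold_warnings.append(
                f"fold {i} ({s.sample_ids[i]}): a class is absent from training"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_plsda(
                train,
                A=A,
                autoscale=autoscale,
                tol=tol,
                max_iter=max_iter,
                class_labels=class_labels,
            )
        scores[i] = model.predict_response(s.intensities[i])
        keep[i] = True
    return scores, fold_warnings


def q2_press(
    s: SpectraSet,
    A: int,
    autoscale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> float:
    """Predicted variation Q² = 1 - PRESS/TSS over leave-one-out folds."""
    class_labels = s.class_labels
    coding = encode_dummy(s.origins, class_labels=class_labels)
    scores, _ = _loo_held_out_scores(s, A, autoscale, class_labels, tol, max_iter)
    press = np.linalg.norm(coding.Y - scores) ** 2
    tss = np.linalg.norm(coding.Y - coding.Y.mean(axis=0)) ** 2
    if tss == 0:
        raise ValueError("degenerate response: zero total sum of squares")
    return 1.0 - press / tss


def loo_cv(
    s: SpectraSet,
    A: int | None = None,
    autoscale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> CVReport:
    """Leave-one-out cross-validation of the PLS-DA classifier.

    For each sample the model (including centring/scaling) is refit on the
    remaining n - 1 samples and applied to the held-out sample.  The
    report aggregates the n held-out assignments into a confusion matrix
    with per-class metrics, computes R² from the full-data fit and Q² from
    the held-out residuals, and builds one-vs-rest ROC curves from the
    held-out dummy scores.  Deterministic and independent of sample order.
    """
    class_labels = s.class_labels
    k = len(class_labels)
    if A is None:
        A = k - 1
    if s.n < k + 2:
        raise ValueError(f"need n >= k + 2 samples for LOO, got n={s.n}, k={k}")
    if A > s.n - 2:
        raise ValueError(f"A={A} too large for LOO with n={s.n}")

    coding = encode_dummy(s.origins, class_labels=class_labels)
    scores, fold_warnings = _loo_held_out_scores(
        s, A, autoscale, class_labels, tol, max_iter
    )
    assigned = [class_labels[j] for j in np.argmax(scores, axis=1)]
    cm = confusion_matrix(s.origins, assigned, class_labels=class_labels)
    metrics = confusion_metrics(cm)

    press = np.linalg.norm(coding.Y - scores) ** 2
    tss = np.linalg.norm(coding.Y - coding.Y.mean(axis=0)) ** 2
    q2 = 1.0 - press / tss

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        full_model = fit_plsda(
            s, A=A, autoscale=autoscale, tol=tol, max_iter=max_iter
        )
    r2 = r2_explained(s, full_model)

    roc = [
        roc_auc(scores[:, j], s.origins == label, class_label=label)
        for j, label in enumerate(class_labels)
    ]
    return CVReport(
        A=A,
        confusion=cm,
        metrics=metrics,
        r2=r2,
        q2=q2,
        roc=roc,
        held_out_scores=scores,
        settings={
            "A": A,
            "autoscale": autoscale,
            "convergence_tol": tol,
            "max_iter": max_iter,
            "n": s.n,
            "p": s.p,
            "class_labels": class_labels,
        },
        fold_warnings=fold_warnings,
    )


@dataclass
class ComponentScan:
    """LOO summaries for A = 1..A_max, with the k-1 default flagged."""

    table: pd.DataFrame  # columns: A, accuracy, r2, q2, auc_<class>..., mean_auc
    a_default: int  # the k - 1 rule
    a_best_q2: int  # argmax of Q² over the scanned range


def component_scan(
    s: SpectraSet,
    A_max: int | None = None,
    autoscale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> ComponentScan:
    """Evaluate LOO performance for every component count 1..A_max.

    ``A_max`` defaults to k - 1.  The returned table carries one row per
    A with accuracy, R², Q² and per-class AUC; ``a_default`` flags the
    k - 1 rule and ``a_best_q2`` the empirical Q² optimum for comparison.
    """
    k = len(s.class_labels)
    if A_max is None:
        A_max = k - 1
    if not 1 <= A_max <= s.n - 2:
        raise ValueError(f"A_max={A_max} outside [1, n-2]")
    rows = []
    for A in range(1, A_max + 1):
        report = loo_cv(s, A=A, autoscale=autoscale, tol=tol, max_iter=max_iter)
        row = {"A": A, "accuracy": report.accuracy, "r2": report.r2, "q2": report.q2}
        aucs = report.auc_by_class()
        for label, auc in aucs.items():
            row[f"auc_{label}"] = auc
        row["mean_auc"] = float(np.mean(list(aucs.values())))
        rows.append(row)
    table = pd.DataFrame(rows)
    best = int(table.loc[table["q2"].idxmax(), "A"])
    return ComponentScan(table=table, a_default=k - 1, a_best_q2=best)
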