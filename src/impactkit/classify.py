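"""RBF-SVM impact classifier: training, leave-one-out validation, greedy
forward feature selection, evaluation metrics and curves, and the
peak-acceleration threshold baseline.

Sequential forward selection scores every candidate feature set by a
leave-one-out cross-validation cost (1 - AUC or 1 - F-measure) rather than
a training-set fit, so the selection itself is protected against
overfitting the small labeled cohort.  Standardisation statistics are
recomputed inside every fold: the held-out sample never leaks into them.

Metrics follow the standard confusion-matrix definitions
(sensitivity = TP/(TP+FN), precision = TP/(TP+FP),
specificity = TN/(TN+FP), accuracy = (TP+TN)/n, and the F-measure as the
harmonic mean of sensitivity and precision).  Reported percentages round
to one decimal, half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

try:                                    # fast path for the LOOCV inner loop
    from sklearn.svm import _libsvm
    _libsvm.set_verbosity_wrap(0)
except ImportError:                     # pragma: no cover
    _libsvm = None

from .registry import FEATURE_INDEX

POSITIVE, NEGATIVE = "impact", "nonimpact"


def _to_pm1(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        return np.where(y == POSITIVE, 1, -1)
    return np.where(np.asarray(y, dtype=float) > 0, 1, -1)


@dataclass
class ClassifierConfig:
    c: float = 1.0
    gamma: float | None = None      # None -> 1/n_features (post-standardisation)
    standardize: bool = True
    cost: str = "auc"               # 'auc' or 'f_measure'
    max_features: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("C must be positive")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.cost not in ("auc", "f_measure"):
            raise ValueError("cost must be 'auc' or 'f_measure'")


@dataclass
class TrainedClassifier:
    """Serialisable RBF-SVM decision function over selected features."""

    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    support_vectors: np.ndarray     # (n_sv, d), standardised
    dual_coef: np.ndarray           # (n_sv,)
    intercept: float
    gamma: float
    c: float
    threshold: float = 0.0

    def decision_values(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Z = (X - self.means) / self.scales
        sq = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * sq) @ self.dual_coef + self.intercept

    def predict(self, X) -> np.ndarray:
        return np.where(self.decision_values(X) >= self.threshold,
                        POSITIVE, NEGATIVE)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "means": self.means.tolist(), "scales": self.scales.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept, "gamma": self.gamma, "c": self.c,
            "threshold": self.threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedClassifier":
        return cls(
            feature_names=list(d["feature_names"]),
            means=np.asarray(d["means"], dtype=float),
            scales=np.asarray(d["scales"], dtype=float),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]), gamma=float(d["gamma"]),
            c=float(d["c"]), threshold=float(d.get("threshold", 0.0)))


@dataclass
class EvaluationReport:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f_measure: float
    degenerate: bool = False
    roc_points: np.ndarray | None = None    # (k, 2) of (FPR, TPR)
    auc_roc: float | None = None
    pr_points: np.ndarray | None = None     # (k, 2) of (recall, precision)
    auc_pr: float | None = None


def round_percent(fraction: float) -> float:
    """One-decimal percentage, rounding half away from zero (report format)."""
    return math.floor(abs(fraction) * 1000.0 + 0.5) / 10.0 * math.copysign(1, fraction)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> EvaluationReport:
    """Confusion-matrix rates; undefined quotients report 0 and a flag."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    n = tp + tn + fp + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    degenerate = False

    def _ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    sens = _ratio(tp, tp + fn)
    prec = _ratio(tp, tp + fp)
    spec = _ratio(tn, tn + fp)
    acc = (tp + tn) / n
    f = _ratio_f(sens, prec)
    if sens + prec == 0:
        degenerate = True
    return EvaluationReport(tp=tp, tn=tn, fp=fp, fn=fn, sensitivity=sens,
                            specificity=spec, accuracy=acc, precision=prec,
                            f_measure=f, degenerate=degenerate)


def _ratio_f(sensitivity: float, precision: float) -> float:
    if sensitivity + precision == 0:
        return 0.0
    return 2 * sensitivity * precision / (sensitivity + precision)


# ---------------------------------------------------------------------------
# training / LOOCV

def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0)
    scales[scales == 0] = 1.0
    return means, scales


def _fit_decision(Ztr: np.ndarray, ytr_pm1: np.ndarray, Zte: np.ndarray,
                  gamma: float, C: float) -> float:
    """RBF-SVM decision value for one test point.

    Uses libsvm directly when available (identical solution to
    ``sklearn.svm.SVC``, asserted in tests, at a fraction of the per-fit
    overhead — this sits inside the selection loop's n-fold LOOCV);
    otherwise falls back to SVC.
    """
    if _libsvm is not None:
        # encode labels exactly as SVC does (sorted classes -> 0/1) so the
        # sign convention matches after the binary negation
        y01 = np.ascontiguousarray((ytr_pm1 > 0).astype(np.float64))
        support, SV, nSV, sv_coef, intercept, probA, probB, *_ = _libsvm.fit(
            np.ascontiguousarray(Ztr), y01, svm_type=0, kernel="rbf",
            C=C, gamma=gamma)
        dec = _libsvm.decision_function(
            np.ascontiguousarray(Zte), support, SV, nSV, sv_coef, intercept,
            probA, probB, svm_type=0, kernel="rbf", gamma=gamma)
        return float(-dec.ravel()[0])
    svc = SVC(C=C, kernel="rbf", gamma=gamma).fit(Ztr, ytr_pm1)
    return float(svc.decision_function(Zte)[0])


def train_rbf_svm(X, y, cfg: ClassifierConfig | None = None,
                  feature_names: list[str] | None = None) -> TrainedClassifier:
    """Fit the RBF-SVM on the full dataset (decision >= 0 -> impact)."""
    cfg = cfg or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    ypm = _to_pm1(y)
    if len(np.unique(ypm)) < 2:
        raise ValueError("training requires both classes present")
    if cfg.standardize:
        means, scales = _standardize_fit(X)
    else:
        means, scales = np.zeros(X.shape[1]), np.ones(X.shape[1])
    Z = (X - means) / scales
    gamma = cfg.gamma if cfg.gamma is not None else 1.0 / X.shape[1]
    svc = SVC(C=cfg.c, kernel="rbf", gamma=gamma).fit(Z, ypm)
    return TrainedClassifier(
        feature_names=list(feature_names) if feature_names is not None
        else [f"f{i}" for i in range(X.shape[1])],
        means=means, scales=scales,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]), gamma=gamma, c=cfg.c)


def loocv_decision_values(X, y, cfg: ClassifierConfig | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Held-out decision value per sample (n folds).

    Standardisation and the SVM fit in each fold use only the n-1 training
    samples.  A fold whose training labels collapse to a single class is
    flagged and scored 0 (prior-free default), conserving n.
    """
    cfg = cfg or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    ypm = _to_pm1(y)
    n = len(ypm)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    gamma = cfg.gamma if cfg.gamma is not None else 1.0 / X.shape[1]
    values = np.zeros(n)
    flagged = np.zeros(n, dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        ytr = ypm[mask]
        if len(np.unique(ytr)) < 2:
            flagged[i] = True
            continue
        Xtr = X[mask]
        if cfg.standardize:
            means, scales = _standardize_fit(Xtr)
        else:
            means, scales = np.zeros(X.shape[1]), np.ones(X.shape[1])
        values[i] = _fit_decision((Xtr - means) / scales, ytr,
                                  (X[i:i + 1] - means) / scales,
                                  gamma, cfg.c)
    return values, flagged


# ---------------------------------------------------------------------------
# curves

def roc_pr_curves(scores, y) -> EvaluationReport:
    """ROC and PR curves by threshold sweep over the unique scores.

    Predictions are positive at score >= threshold; tied scores share one
    threshold.  Areas are trapezoidal; the PR curve is extended to
    recall = 0 at its first precision value.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    ypm = _to_pm1(y)
    n_pos = int((ypm == 1).sum())
    n_neg = int((ypm == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/PR curves require both classes")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = (ypm[order] == 1).astype(int)
    tp_cum = np.cumsum(sorted_pos)
    fp_cum = np.cumsum(1 - sorted_pos)
    # last index of each tied-score group
    distinct = np.nonzero(np.diff(sorted_scores, append=np.nan))[0]
    tp = tp_cum[distinct]
    fp = fp_cum[distinct]

    tpr = np.concatenate([[0.0], tp / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], fp / n_neg, [1.0]])
    auc_roc = float(np.trapezoid(tpr, fpr))

    recall = tp / n_pos
    precision = tp / (tp + fp)
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[precision[0]], precision])
    sort_r = np.argsort(recall, kind="stable")
    auc_pr = float(np.trapezoid(precision[sort_r], recall[sort_r]))

    # confusion at the default threshold 0
    pred_pos = scores >= 0
    report = confusion_metrics(
        tp=int(((ypm == 1) & pred_pos).sum()),
        tn=int(((ypm == -1) & ~pred_pos).sum()),
        fp=int(((ypm == -1) & pred_pos).sum()),
        fn=int(((ypm == 1) & ~pred_pos).sum()))
    report.roc_points = np.column_stack([fpr, tpr])
    report.auc_roc = auc_roc
    report.pr_points = np.column_stack([recall[sort_r], precision[sort_r]])
    report.auc_pr = auc_pr
    return report


def baseline_threshold_curves(peak_acc_magnitude, y) -> EvaluationReport:
    """Peak linear-acceleration thresholding baseline (same sweep semantics)."""
    return roc_pr_curves(np.asarray(peak_acc_magnitude, dtype=float), y)


# ---------------------------------------------------------------------------
# sequential forward selection

def _loocv_cost(X, y, cfg: ClassifierConfig) -> float:
    values, _ = loocv_decision_values(X, y, cfg)
    report = roc_pr_curves(values, y)
    if cfg.cost == "auc":
        return 1.0 - report.auc_roc
    return 1.0 - report.f_measure


def sequential_forward_selection(
        X, y, cfg: ClassifierConfig | None = None,
        feature_names: list[str] | None = None,
) -> tuple[list[int], list[float]]:
    """Greedy forward selection under the LOOCV cost.

    At each step every unselected feature is scored by the LOOCV cost of
    the candidate set; the best candidate is accepted only if it strictly
    improves the cost, ties breaking toward the lowest registry index.
    Returns (selected column indices in acceptance order, cost trace).
    """
    cfg = cfg or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    d = X.shape[1]
    if feature_names is not None:
        registry_rank = [FEATURE_INDEX.get(nm, d + j)
                         for j, nm in enumerate(feature_names)]
    else:
        registry_rank = list(range(d))

    selected: list[int] = []
    trace: list[float] = []
    current = np.inf
    while len(selected) < min(cfg.max_features, d):
        best_j, best_cost = None, np.inf
        for j in sorted(range(d), key=lambda k: registry_rank[k]):
            if j in selected:
                continue
            cost = _loocv_cost(X[:, selected + [j]], y, cfg)
            if cost < best_cost:
                best_j, best_cost = j, cost
        if best_j is None or not best_cost < current:
            break
        selected.append(best_j)
        trace.append(best_cost)
        current = best_cost
        if current <= 0.0:
            break
    return selected, trace
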