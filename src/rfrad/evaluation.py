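"""SVM classification with incremental feature sweep and LOOCV evaluation.

The classifier is a soft-margin SVM with Gaussian RBF kernel at fixed
hyperparameters (C = 0.8, gamma = 1), evaluated by leave-one-out
cross-validation: in each fold the features are re-standardised on the
n-1 training patients, the SVM refit, and the held-out patient scored
with the signed decision value ("radiomics score").  The feature
ordering is computed once on the full table and reused across folds
(single-ranking protocol) — a known source of optimism (see the
methods note) that is kept deliberately.

Reported metrics: ACC/SENS/SPEC at decision threshold 0 (positives =
label 1), AUC via the Mann-Whitney statistic with a stratified-bootstrap
95% CI, the precision-recall curve with its break-even point (BEP), and
a one-way ANOVA (equivalently Tukey HSD for two groups) comparing the
scores of the two classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve
from sklearn.svm import SVC

from .rf_core import ValidationError
from .selection import SRCRanking

__all__ = [
    "SweepResult",
    "ModelReport",
    "train_svm",
    "loocv_scores",
    "sweep_feature_count",
    "binary_metrics",
    "roc_auc",
    "prc_bep",
    "compare_scores",
    "evaluate_model",
]

DEFAULT_C = 0.8
DEFAULT_GAMMA = 1.0


@dataclass
class SweepResult:
    """Per-feature-count LOOCV metrics (percent) and the chosen count."""

    k_values: np.ndarray
    acc: np.ndarray
    auc: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    best_k: int


@dataclass
class ModelReport:
    """Full evaluation of one model variant at its chosen feature count."""

    scores: np.ndarray  # per-patient LOOCV decision values
    predictions: np.ndarray
    acc: float
    sens: float
    spec: float
    auc: float
    auc_ci: tuple[float, float]
    roc: tuple[np.ndarray, np.ndarray]  # (FPR, TPR)
    prc: tuple[np.ndarray, np.ndarray]  # (recall, precision)
    bep: float
    anova_p: float
    tukey_p: float
    sweep: SweepResult | None = None


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).ravel().astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be 0/1")
    return y


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    tol: float = 1e-3,
) -> SVC:
    """Fit the RBF-kernel SVM; ``decision_function`` is the signed score."""
    X = np.asarray(X, dtype=np.float64)
    y = _check_labels(y)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("need at least one feature")
    if np.unique(y).size < 2:
        raise ValidationError("training data must contain both classes")
    clf = SVC(C=C, gamma=gamma, kernel="rbf", tol=tol)
    clf.fit(X, y)
    return clf


def loocv_scores(
    X: np.ndarray,
    y: np.ndarray,
    ranking: SRCRanking | np.ndarray,
    k: int,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out decision scores on the top-``k`` ranked features.

    Standardisation statistics are recomputed from each training fold.
    Returns ``(scores, predicted_labels)`` of length n.
    """
    X = np.asarray(X, dtype=np.float64)
    y = _check_labels(y)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("LOOCV needs n >= 3")
    if np.unique(y).size < 2:
        raise ValidationError("cohort contains a single class")
    order = ranking.order if isinstance(ranking, SRCRanking) else np.asarray(ranking)
    cols = order[:k]
    if cols.size < 1:
        raise ValidationError("k must be >= 1")
    Xk = X[:, cols]
    scores = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        mu = Xk[tr].mean(axis=0)
        sd = Xk[tr].std(axis=0)
        sd[sd == 0] = 1.0
        clf = SVC(C=C, gamma=gamma, kernel="rbf")
        clf.fit((Xk[tr] - mu) / sd, y[tr])
        s = float(clf.decision_function(((Xk[i] - mu) / sd)[None, :])[0])
        # sklearn orients the decision function towards clf.classes_[1]
        scores[i] = s if clf.classes_[-1] == 1 else -s
    return scores, (scores > 0).astype(int)


def binary_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.0):
    """(ACC, SENS, SPEC) in percent at a fixed decision threshold."""
    y = _check_labels(labels)
    if np.unique(y).size < 2:
        raise ValidationError("both classes required")
    pred = (np.asarray(scores).ravel() > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = 100.0 * (tp + tn) / y.size
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    return acc, sens, spec


def sweep_feature_count(
    X: np.ndarray,
    y: np.ndarray,
    ranking: SRCRanking | np.ndarray,
    k_max: int,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
) -> SweepResult:
    """LOOCV metrics for every top-k feature set, k = 1..k_max.

    ``best_k`` maximises AUC; ties prefer higher ACC, then smaller k.
    """
    order = ranking.order if isinstance(ranking, SRCRanking) else np.asarray(ranking)
    if k_max > order.size:
        raise ValidationError("k_max exceeds the number of features")
    ks = np.arange(1, k_max + 1)
    accs, aucs, senss, specs = [], [], [], []
    for k in ks:
        scores, _ = loocv_scores(X, y, order, int(k), C=C, gamma=gamma)
        a, se, sp = binary_metrics(scores, y)
        accs.append(a)
        senss.append(se)
        specs.append(sp)
        aucs.append(100.0 * roc_auc_score(_check_labels(y), scores))
    accs, aucs = np.array(accs), np.array(aucs)
    # lexicographic argmax: AUC desc, ACC desc, k asc
    best = min(
        range(len(ks)), key=lambda i: (-round(aucs[i], 10), -round(accs[i], 10), ks[i])
    )
    return SweepResult(
        k_values=ks,
        acc=accs,
        auc=aucs,
        sens=np.array(senss),
        spec=np.array(specs),
        best_k=int(ks[best]),
    )


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
):
    """ROC curve, Mann-Whitney AUC and stratified-bootstrap 95% CI.

    Returns ``(fpr, tpr, auc, (lo, hi))`` with AUC in [0, 1]; ties between
    positive and negative scores count one half.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if np.unique(y).size < 2:
        raise ValidationError("both classes required")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    pos = s[y == 1]
    neg = s[y == 0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        yy = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
        boots[b] = roc_auc_score(yy, np.concatenate([bp, bn]))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return fpr, tpr, auc, (float(lo), float(hi))


def prc_bep(scores: np.ndarray, labels: np.ndarray):
    """Precision-recall curve and its break-even point.

    The BEP is the common value where precision equals recall, linearly
    interpolated between the two adjacent threshold points where the sign
    of precision - recall flips; when the curve never crosses, the point
    minimising |precision - recall| is used directly.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if not np.any(y == 1):
        raise ValidationError("at least one positive required")
    precision, recall, thresholds = precision_recall_curve(y, s)
    # drop the artificial (recall 0, precision 1) terminal point for BEP
    p = precision[:-1]
    r = recall[:-1]
    diff = p - r
    bep = None
    for a in range(len(diff) - 1):
        if diff[a] == 0:
            bep = float(p[a])
            break
        if diff[a] * diff[a + 1] < 0:
            t = diff[a] / (diff[a] - diff[a + 1])
            bep = float(p[a] + t * (p[a + 1] - p[a]))
            break
    if bep is None:
        if diff[-1] == 0:
            bep = float(p[-1])
        else:
            bep = float(p[np.argmin(np.abs(diff))])
    return recall, precision, float(bep)


def compare_scores(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA p-value between the two label groups (+ Tukey HSD p).

    With two groups the ANOVA F-test is the squared pooled t-test and
    Tukey's HSD reduces to the same comparison; both p-values are
    returned as ``(anova_p, tukey_p)``.
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=np.float64).ravel()
    g0, g1 = s[y == 0], s[y == 1]
    if g0.size < 2 or g1.size < 2:
        raise ValidationError("each group needs >= 2 scores")
    anova = stats.f_oneway(g0, g1)
    tukey = stats.tukey_hsd(g0, g1)
    return float(anova.pvalue), float(tukey.pvalue[0, 1])


def evaluate_model(
    X: np.ndarray,
    y: np.ndarray,
    ranking: SRCRanking | np.ndarray,
    k_max: int,
    C: float = DEFAULT_C,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
    n_boot: int = 2000,
) -> ModelReport:
    """Sweep feature counts, pick the best k, and report full metrics."""
    sweep = sweep_feature_count(X, y, ranking, k_max, C=C, gamma=gamma)
    scores, pred = loocv_scores(X, y, ranking, sweep.best_k, C=C, gamma=gamma)
    acc, sens, spec = binary_metrics(scores, y)
    fpr, tpr, auc, ci = roc_auc(scores, y, n_boot=n_boot, seed=seed)
    recall, precision, bep = prc_bep(scores, y)
    anova_p, tukey_p = compare_scores(scores, y)
    return ModelReport(
        scores=scores,
        predictions=pred,
        acc=acc,
        sens=sens,
        spec=spec,
        auc=100.0 * auc,
        auc_ci=ci,
        roc=(fpr, tpr),
        prc=(recall, precision),
        bep=bep,
        anova_p=anova_p,
        tukey_p=tukey_p,
        sweep=sweep,
    )
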