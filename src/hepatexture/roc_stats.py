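"""ROC evaluation statistics built on the Hanley closed-form machinery.

AUROC is computed by the Mann-Whitney formulation (ties counted one half);
its standard error is the Hanley-McNeil closed form

    SE^2 = [A(1-A) + (n1-1)(Q1 - A^2) + (n0-1)(Q2 - A^2)] / (n1 * n0)

with Q1 = A/(2-A) and Q2 = 2A^2/(1+A).  Two curves are compared with the
z statistic (A1-A2)/sqrt(SE1^2 + SE2^2 - 2 r SE1 SE2); for paired designs
r is estimated from the average of the within-class Pearson correlations
between the two score vectors, for unpaired designs r = 0.  Threshold
metrics use the strict "positive when score > threshold" rule everywhere,
matching the published 0.5 cut-offs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCResult",
    "ThresholdMetrics",
    "auroc_hanley",
    "hanley_se",
    "compare_auroc",
    "threshold_metrics",
    "best_cutoff",
    "sample_size_auroc",
    "spearman",
]


@dataclass(frozen=True)
class ROCResult:
    auroc: float
    se: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    curve: np.ndarray  # (1 - Sp, Se) pairs, monotone non-decreasing


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None


def _split(scores, labels):
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def mann_whitney_auc(scores, labels) -> float:
    """AUROC as the tie-corrected Mann-Whitney probability."""
    pos, neg = _split(scores, labels)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[:len(pos)].sum()
    n1, n0 = len(pos), len(neg)
    u = r_pos - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def hanley_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an empirical AUROC."""
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def auroc_hanley(scores, labels) -> ROCResult:
    """AUROC with Hanley SE, normal 95 % CI (clipped), and the ROC curve."""
    pos, neg = _split(scores, labels)
    a = mann_whitney_auc(scores, labels)
    se = hanley_se(a, len(pos), len(neg))
    lo, hi = max(0.0, a - 1.96 * se), min(1.0, a + 1.96 * se)
    fpr, tpr, _ = _sk_roc_curve(np.asarray(labels), np.asarray(scores))
    return ROCResult(auroc=a, se=se, ci95=(lo, hi),
                     n_pos=len(pos), n_neg=len(neg),
                     curve=np.column_stack([fpr, tpr]))


def _within_class_r(a, b, labels) -> float:
    """Average Pearson correlation of two score vectors within each class."""
    a = np.asarray(a, np.float64)
    b = np.asarray(b, np.float64)
    y = np.asarray(labels)
    rs = []
    for cls in (0, 1):
        sa, sb = a[y == cls], b[y == cls]
        if len(sa) > 1 and sa.std() > 0 and sb.std() > 0:
            rs.append(float(np.corrcoef(sa, sb)[0, 1]))
    return float(np.mean(rs)) if rs else 0.0


def compare_auroc(scores_a, scores_b, labels, paired: bool = True,
                  labels_b=None) -> tuple[float, float]:
    """z statistic and two-sided p-value for the difference of two AUROCs.

    Paired mode requires both score vectors on the same subjects and
    estimates the AUROC correlation r from the average within-class score
    correlation; unpaired mode (``labels_b`` for the second sample) sets
    r = 0.
    """
    a1 = auroc_hanley(scores_a, labels)
    if paired:
        if len(np.asarray(scores_a)) != len(np.asarray(scores_b)):
            raise ValueError("paired comparison needs equal-length scores")
        a2 = auroc_hanley(scores_b, labels)
        r = _within_class_r(scores_a, scores_b, labels)
    else:
        a2 = auroc_hanley(scores_b, labels if labels_b is None else labels_b)
        r = 0.0
    var = a1.se ** 2 + a2.se ** 2 - 2.0 * r * a1.se * a2.se
    if var <= 0:
        return 0.0, 1.0
    z = (a1.auroc - a2.auroc) / math.sqrt(var)
    p = 2.0 * (1.0 - sps.norm.cdf(abs(z)))
    return float(z), float(p)


def threshold_metrics(scores, labels, threshold: float) -> ThresholdMetrics:
    """Confusion counts and Se/Sp/PPV/NPV at a fixed cut-off.

    Positive call = score strictly greater than the threshold.  PPV/NPV
    are ``None`` when their denominator is empty.
    """
    _split(scores, labels)  # validates classes
    s = np.asarray(scores, np.float64)
    y = np.asarray(labels).astype(int)
    call = s > threshold
    tp = int(np.sum(call & (y == 1)))
    fp = int(np.sum(call & (y == 0)))
    tn = int(np.sum(~call & (y == 0)))
    fn = int(np.sum(~call & (y == 1)))
    return ThresholdMetrics(
        threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp else None,
        npv=tn / (tn + fn) if tn + fn else None)


def best_cutoff(scores, labels) -> float:
    """Youden-optimal threshold over midpoints of adjacent distinct scores.

    Ties in J = Se + Sp - 1 are broken toward the threshold nearest 0.5
    (then toward the smaller threshold).
    """
    _split(scores, labels)
    s = np.unique(np.asarray(scores, np.float64))
    if len(s) == 1:
        return float(s[0])
    cands = (s[:-1] + s[1:]) / 2.0
    best_t, best_j = None, -np.inf
    for t in cands:
        m = threshold_metrics(scores, labels, t)
        j = m.sensitivity + m.specificity - 1.0
        if (j > best_j + 1e-12
                or (abs(j - best_j) <= 1e-12
                    and abs(t - 0.5) < abs(best_t - 0.5) - 1e-12)):
            best_t, best_j = float(t), j
    return best_t


def sample_size_auroc(auc_null: float, auc_alt: float, alpha: float = 0.05,
                      power: float = 0.80, prevalence: float = 0.5,
                      n_max: int = 100000) -> int:
    """Smallest total n detecting the AUROC difference by a two-sided z-test.

    Subjects split by prevalence into positives/negatives; both AUROCs use
    Hanley standard errors and the curves are treated as uncorrelated
    (r = 0), a conservative choice for paired designs.
    """
    for a in (auc_null, auc_alt):
        if not 0.5 <= a <= 1.0:
            raise ValueError("AUROCs must lie in [0.5, 1]")
    if auc_null == auc_alt:
        raise ValueError("the two AUROCs must differ")
    if not 0 < alpha < 1 or not 0 < power < 1 or not 0 < prevalence < 1:
        raise ValueError("alpha, power and prevalence must lie in (0, 1)")
    z_a = sps.norm.ppf(1.0 - alpha / 2.0)
    z_b = sps.norm.ppf(power)
    delta = abs(auc_alt - auc_null)
    for n in range(4, n_max + 1):
        n_pos = max(1, int(round(n * prevalence)))
        n_neg = n - n_pos
        if n_neg < 1:
            continue
        se = math.sqrt(hanley_se(auc_null, n_pos, n_neg) ** 2
                       + hanley_se(auc_alt, n_pos, n_neg) ** 2)
        if delta / se >= z_a + z_b:
            return n
    raise ValueError("no feasible n below n_max")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with t-test p."""
    x = np.asarray(x, np.float64)
    y = np.asarray(y, np.float64)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
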