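"""Shock classification against fixed cutoffs and the statistical
evaluation suite: confusion-matrix diagnostics, ROC/AUC with the
Youden-optimal associated criterion, Mann-Whitney U, Spearman rank
correlation, Cohen's d, the shock index, and the clinical screening
rule.

Default cutoffs: roi_diff < 6966.43, roi_ratio < 0.36, SBP < 95 mmHg,
MAP < 65 mmHg, each flagging shock when the value falls strictly below
the cutoff (ties are negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "ClassifierConfig",
    "ConfusionMatrix",
    "RocResult",
    "DEFAULT_CUTOFFS",
    "classify",
    "confusion",
    "diagnostics",
    "invert_summary",
    "roc",
    "mann_whitney_u",
    "spearman",
    "cohens_d",
    "shock_index",
    "screen_shock",
]

DEFAULT_CUTOFFS: dict[str, tuple[float, str]] = {
    "roi_diff": (6966.43, "below"),
    "roi_ratio": (0.36, "below"),
    "SBP": (95.0, "below"),
    "MAP": (65.0, "below"),
}


@dataclass(frozen=True)
class ClassifierConfig:
    metric: str
    cutoff: float
    positive_if: str = "below"

    def __post_init__(self) -> None:
        if not math.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        if self.positive_if not in ("below", "above"):
            raise ValueError("positive_if must be 'below' or 'above'")

    @classmethod
    def default_for(cls, metric: str) -> "ClassifierConfig":
        cutoff, side = DEFAULT_CUTOFFS[metric]
        return cls(metric=metric, cutoff=cutoff, positive_if=side)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0:
                raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    associated_criterion: float
    p_value: float


def classify(values, config: ClassifierConfig) -> np.ndarray:
    """Predicted labels: True = positive (shock).

    Positive iff the value falls strictly below (or above) the cutoff;
    values exactly at the cutoff are negative.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("metric values must be finite")
    if config.positive_if == "below":
        return v < config.cutoff
    return v > config.cutoff


def confusion(pred, truth) -> ConfusionMatrix:
    """Cross-tabulate boolean predicted vs true labels."""
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("pred and truth must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def diagnostics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, recall, precision and F1; metrics with a zero
    denominator are returned as None (flagged, never silently 0)."""
    out: dict[str, float | None] = {}
    out["accuracy"] = (cm.tp + cm.tn) / cm.total
    out["recall"] = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    out["precision"] = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    if out["recall"] is not None and out["precision"] is not None and (
        out["recall"] + out["precision"] > 0
    ):
        out["f1"] = (
            2.0 * out["precision"] * out["recall"] / (out["precision"] + out["recall"])
        )
    else:
        out["f1"] = None
    return out


def invert_summary(
    accuracy: float, recall: float, n_pos: int, n_neg: int, tol: float = 0.5
) -> ConfusionMatrix:
    """Reconstruct the integer confusion matrix implied by a printed
    accuracy and recall for known class sizes.

    tp = round(recall * n_pos); tn = round(accuracy * n) - tp;
    fn = n_pos - tp; fp = n_neg - tn.  Raises if the rounding residuals
    exceed ``tol`` or the implied counts are not valid non-negative
    integers.
    """
    n = n_pos + n_neg
    tp_f = recall * n_pos
    tp = round(tp_f)
    correct_f = accuracy * n
    tn = round(correct_f) - tp
    if abs(tp_f - tp) > tol or abs(correct_f - (tp + tn)) > tol:
        raise ValueError(
            f"no integer matrix within tolerance: residuals "
            f"{tp_f - tp:+.3f} (tp), {correct_f - tp - tn:+.3f} (tp+tn)"
        )
    fn = n_pos - tp
    fp = n_neg - tn
    if min(tp, fp, fn, tn) < 0:
        raise ValueError(
            f"implied counts negative: tp={tp}, fp={fp}, fn={fn}, tn={tn}"
        )
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x via midrank sums (ties counted half)."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = np.sum(ranks[: x.size])
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney_u(x, y) -> dict[str, float]:
    """Two-sided Mann-Whitney U test.

    Exact permutation enumeration when n1 + n2 <= 12; otherwise the
    normal approximation with tie correction and continuity correction.
    Returns ``{"U": ..., "p_two_sided": ...}`` with U the statistic of
    the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= 12:
        combined = np.concatenate([x, y])
        dev = abs(u - mu)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(combined[mask], combined[~mask])
            if abs(u_perm - mu) >= dev - 1e-12:
                count += 1
            total += 1
        return {"U": u, "p_two_sided": count / total}

    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return {"U": u, "p_two_sided": 1.0}
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return {"U": u, "p_two_sided": float(2.0 * stats.norm.sf(z))}


def spearman(x, y) -> dict[str, float]:
    """Spearman rank correlation (Pearson on midranks) with a two-sided
    t-approximation p-value on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rs) >= 1.0:
        return {"rs": rs, "p_two_sided": 0.0}
    t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return {"rs": rs, "p_two_sided": p}


def roc(scores, truth, positive_if: str = "below") -> RocResult:
    """Empirical ROC curve, trapezoid AUC, and the Youden-optimal
    associated criterion.

    With ``positive_if='below'`` a case is called positive when its
    score is <= the threshold (matching a classify-below rule evaluated
    at observed values).  The AUC equals the Mann-Whitney concordance
    probability with ties counted half; the p-value tests AUC != 0.5
    through the normal approximation on the U statistic.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if positive_if not in ("below", "above"):
        raise ValueError("positive_if must be 'below' or 'above'")

    oriented = -s if positive_if == "below" else s  # higher => more positive
    thresholds = np.unique(s)
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = s <= thr if positive_if == "below" else s >= thr
        sens[i] = np.sum(pred & t) / n_pos
        spec[i] = np.sum(~pred & ~t) / n_neg

    # AUC via the rank (Mann-Whitney) estimate, ties counted half.
    ranks = stats.rankdata(oriented)
    r_pos = np.sum(ranks[t])
    u_pos = r_pos - n_pos * (n_pos + 1) / 2.0
    auc = float(u_pos / (n_pos * n_neg))

    j = sens + spec - 1.0
    associated = float(thresholds[int(np.argmax(j))])

    p = mann_whitney_u(s[t], s[~t])["p_two_sided"]
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        associated_criterion=associated,
        p_value=p,
    )


def cohens_d(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> float:
    """Cohen's d = (mean_b - mean_a) / pooled SD with the
    (n-1)-weighted pooled variance.

    Call with the study group as ``a`` and the control group as ``b``
    for the control-minus-study sign convention.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    pooled = math.sqrt(
        ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    )
    if pooled == 0:
        if mean_a == mean_b:
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return (mean_b - mean_a) / pooled


def shock_index(hr: float, sbp: float) -> dict[str, float | bool]:
    """Shock index SI = HR / SBP; the flag raises above 0.9."""
    if sbp <= 0:
        raise ValueError("SBP must be positive")
    si = hr / sbp
    return {"SI": si, "flag": si > 0.9}


def screen_shock(record) -> dict[str, object]:
    """Disjunctive clinical screening rule: SBP < 95 mmHg, MAP < 65
    mmHg, or lactate > 2 mmol/L.

    ``record`` is any mapping with optional keys SBP, MAP, lactate
    (missing or NaN values do not fire).  Returns the overall verdict
    and which criteria fired.
    """
    def _get(key):
        v = record.get(key) if hasattr(record, "get") else getattr(record, key, None)
        if v is None:
            return None
        v = float(v)
        return None if math.isnan(v) else v

    fired = []
    sbp = _get("SBP")
    if sbp is not None and sbp < 95.0:
        fired.append("SBP<95")
    map_ = _get("MAP")
    if map_ is not None and map_ < 65.0:
        fired.append("MAP<65")
    lac = _get("lactate")
    if lac is not None and lac > 2.0:
        fired.append("lactate>2")
    return {"shock": bool(fired), "criteria": fired}
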