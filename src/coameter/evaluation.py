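"""Diagnostic-performance evaluation against a gold standard.

A single binary decision against the surgical gold standard yields a 2x2
confusion matrix (positive class: coarctation).  From it:

    accuracy    = (TP + TN) / N
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    AUC         = (sensitivity + specificity) / 2

The AUC of a single binary decision is the two-point trapezoidal ROC
area, hence the balanced mean of sensitivity and specificity.  Agreement
beyond chance is Cohen's kappa, (p_o - p_e) / (1 - p_e) with
marginal-product chance agreement.  Paired measurement methods are
compared with the Wilcoxon signed-rank test (exact null distribution up
to n = 25, normal approximation with tie and continuity corrections
beyond; zero differences dropped, tied ranks averaged).

Reported values are rounded with decimal round-half-even, the rule under
which the computed metrics agree with their conventional 2-decimal
presentations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import UndefinedMetricError

__all__ = [
    "ConfusionMatrix",
    "EvalMetrics",
    "confusion",
    "metrics",
    "cohen_kappa",
    "interpret_kappa",
    "wilcoxon_signed_rank",
    "WilcoxonResult",
    "round_report",
]


def round_report(x: float, decimals: int = 2) -> float:
    """Round for reporting: decimal round-half-even after clearing float dust."""
    if isinstance(x, float) and not math.isfinite(x):
        return x
    d = Decimal(repr(float(x))).quantize(Decimal("1e-10"), rounding=ROUND_HALF_EVEN)
    return float(d.quantize(Decimal(f"1e-{decimals}"), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; positive class is coarctation, truth is the gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: Sequence, truth: Sequence, positive="coa") -> ConfusionMatrix:
    """Cross-tabulate predicted against gold-standard labels.

    Labels must be binary; anything equal to ``positive`` is the positive
    class, and exactly one other label value is allowed.
    """
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    labels = set(pred) | set(truth)
    if len(labels - {positive}) > 1:
        raise ValueError(f"labels are not binary: {sorted(map(str, labels))}")
    tp = fp = fn = tn = 0
    for p, t in zip(pred, truth):
        if t == positive:
            tp += p == positive
            fn += p != positive
        else:
            fp += p == positive
            tn += p != positive
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class EvalMetrics:
    """Full-precision metrics; ``rounded()`` gives the reporting form."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    kappa: float

    def rounded(self, decimals: int = 2) -> "EvalMetrics":
        return EvalMetrics(
            *(round_report(getattr(self, f), decimals) for f in
              ("accuracy", "sensitivity", "specificity", "auc", "kappa"))
        )


def metrics(cm: ConfusionMatrix) -> EvalMetrics:
    """Accuracy, sensitivity, specificity, balanced AUC and kappa from counts.

    Raises :class:`UndefinedMetricError` when a required denominator is
    zero rather than silently reporting 0.
    """
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    if pos == 0:
        raise UndefinedMetricError("sensitivity undefined: no gold-standard positives")
    if neg == 0:
        raise UndefinedMetricError("specificity undefined: no gold-standard negatives")
    sens = cm.tp / pos
    spec = cm.tn / neg
    return EvalMetrics(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=sens,
        specificity=spec,
        auc=(sens + spec) / 2.0,
        kappa=cohen_kappa(cm),
    )


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e)."""
    n = cm.total
    if n == 0:
        raise UndefinedMetricError("empty confusion matrix")
    p_o = (cm.tp + cm.tn) / n
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / (n * n)
    if p_e == 1.0:
        raise UndefinedMetricError("kappa undefined: degenerate marginals (p_e = 1)")
    return (p_o - p_e) / (1.0 - p_e)


def interpret_kappa(k: float) -> str:
    """Agreement grade: good (>= 0.75), fair ([0.4, 0.75)), poor (< 0.4)."""
    if not -1.0 <= k <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {k}")
    if k >= 0.75:
        return "good"
    if k >= 0.4:
        return "fair"
    return "poor"


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # pairs remaining after dropping zero differences
    method: str  # 'exact' or 'normal'


def _exact_sf_table(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of W+ over all sign assignments.

    Tied ranks are averaged, so W+ lives on a half-integer lattice; ranks
    are doubled to make them integers and the distribution built by
    dynamic-programming convolution (2^n enumeration is never needed).
    Returns (support, pmf) on the doubled scale.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    pmf = counts / counts.sum()
    return np.arange(total + 1), pmf


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float] | None = None,
    *,
    exact_n_max: int = 25,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples (or differences).

    With ``b`` given, differences are ``a - b``.  Zero differences are
    dropped; ranks of |d| are averaged over ties.  For n <= ``exact_n_max``
    the p-value comes from the exact null distribution of W+ (valid under
    averaged tied ranks); otherwise from a normal approximation with tie
    correction and a 0.5 continuity correction.

    Raises
    ------
    ValueError
        If all differences are zero (test undefined) or lengths mismatch.
    """
    a = np.asarray(a, dtype=float)
    if b is not None:
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"paired samples differ in length: {a.shape} vs {b.shape}")
        d = a - b
    else:
        d = a
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; the test is undefined")

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_n_max:
        support, pmf = _exact_sf_table(ranks)
        w2 = int(round(2 * w_plus))
        cdf = np.cumsum(pmf)
        p_le = float(cdf[w2])
        p_ge = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(statistic=w_plus, p_value=p, n_used=n, method="exact")

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var == 0:
        raise ValueError("zero variance under ties; the test is undefined")
    # continuity correction: shrink |W+ - mean| by 0.5
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return WilcoxonResult(statistic=w_plus, p_value=p, n_used=n, method="normal")
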