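"""Binary classification metrics and multi-run statistical comparison.

Six confusion-matrix metrics (accuracy, precision/PPV, specificity,
sensitivity, F1, Matthews correlation coefficient) with the positive
class = malignant, a two-sample Wilcoxon rank-sum test with exact
small-sample critical values, and mean/best/worst/std summaries over
repeated runs.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RankSumResult",
    "compute_metrics",
    "rank_sum_test",
    "rank_sum_critical_value",
    "summarize_runs",
    "METRIC_NAMES",
]

METRIC_NAMES = ("acc", "ppv", "spc", "sen", "f1", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The six metrics; ``zero_division`` names those defined as 0 by
    convention because a denominator vanished."""

    acc: float
    ppv: float
    spc: float
    sen: float
    f1: float
    mcc: float
    zero_division: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        d = asdict(self)
        d["zero_division"] = list(self.zero_division)
        return d


def _ratio(num: float, den: float, name: str, flags: list) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(y_true, y_pred) -> tuple[ConfusionCounts, MetricsReport]:
    """Tally the confusion matrix (1 = malignant) and the six metrics.

    Any metric whose denominator is zero is reported as 0 and flagged,
    following the usual Matthews-coefficient convention.
    """
    yt = np.asarray(y_true).ravel()
    yp = np.asarray(y_pred).ravel()
    if yt.size == 0 or yt.size != yp.size:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    for name, v in (("y_true", yt), ("y_pred", yp)):
        if not np.all(np.isin(v, (0, 1))):
            raise ValueError(f"{name} must contain only 0/1 labels")

    tp = int(np.sum((yt == 1) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)

    flags: list[str] = []
    acc = (tp + tn) / counts.total
    ppv = _ratio(tp, tp + fp, "ppv", flags)
    spc = _ratio(tn, tn + fp, "spc", flags)
    sen = _ratio(tp, tp + fn, "sen", flags)
    f1 = _ratio(2.0 * ppv * sen, ppv + sen, "f1", flags)
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc", flags)

    report = MetricsReport(acc=acc, ppv=ppv, spc=spc, sen=sen, f1=f1, mcc=mcc,
                           zero_division=tuple(flags))
    return counts, report


@dataclass(frozen=True)
class RankSumResult:
    """Two-sample Wilcoxon rank-sum outcome.

    ``w1``/``w2`` are the rank sums of the two samples (midranks for
    ties); ``decision`` is "reject" when the null of equal location is
    rejected at significance ``significance``; ``confidence_level`` is
    ``(1 - significance) * 100``.
    """

    n1: int
    n2: int
    w1: float
    w2: float
    decision: str
    significance: float
    confidence_level: float
    p_value: float
    critical_value: float | None
    method: str


def _ranksum_counts(n_small: int, N: int) -> np.ndarray:
    """Number of ``n_small``-subsets of ranks ``1..N`` per rank-sum value.

    Classic subset-sum dynamic program; ``counts[s]`` is the number of
    subsets summing to ``s``.  Sizes here are tiny (N <= 40).
    """
    max_sum = n_small * N
    counts = np.zeros((n_small + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n_small), 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum - r + 1]
    return counts[n_small]


def rank_sum_critical_value(n1: int, n2: int, significance: float) -> int:
    """Largest ``c`` with ``P(W <= c) <= significance/2`` under the null.

    ``W`` is the rank sum of the smaller sample (size ``min(n1, n2)``).
    Exact two-sided small-sample critical value; reject when the smaller
    of the observed rank sum and its reflection is ``<= c``.
    """
    ns, N = min(n1, n2), n1 + n2
    counts = _ranksum_counts(ns, N)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    ok = np.nonzero(cdf <= significance / 2.0)[0]
    if ok.size == 0:
        raise ValueError(
            f"no attainable critical value at significance {significance} "
            f"for sizes ({n1}, {n2})"
        )
    return int(ok[-1])


def _exact_p_value(w_small: float, ns: int, N: int) -> float:
    counts = _ranksum_counts(ns, N)
    total = counts.sum()
    w = int(round(w_small))
    p_low = counts[: w + 1].sum() / total
    p_high = counts[w:].sum() / total
    return min(1.0, 2.0 * min(p_low, p_high))


def rank_sum_test(sample_a, sample_b, significance: float = 0.05) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of equal location.

    Ranks are midranks over the pooled samples, so
    ``w1 + w2 = (n1+n2)(n1+n2+1)/2`` always holds.  For sample sizes up
    to 20 without ties the decision uses the exact null distribution of
    the smaller sample's rank sum (dynamic-program enumeration);
    otherwise a tie-corrected, continuity-corrected normal
    approximation.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    N = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled, method="average")
    w1 = float(ranks[:n1].sum())
    w2 = float(ranks[n1:].sum())

    has_ties = np.unique(pooled).size < N
    w_small = w1 if n1 <= n2 else w2
    ns = min(n1, n2)
    w_reflect = ns * (N + 1) - w_small

    critical_value: float | None = None
    if not has_ties and max(n1, n2) <= 20:
        method = "exact"
        p_value = _exact_p_value(w_small, ns, N)
        critical_value = float(rank_sum_critical_value(n1, n2, significance))
        reject = min(w_small, w_reflect) <= critical_value
    else:
        method = "normal"
        mean_w = ns * (N + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts**3 - tie_counts) / ((N - 1.0) * N)
        var_w = n1 * n2 / 12.0 * ((N + 1.0) - tie_term)
        if var_w == 0.0:
            p_value = 1.0
        else:
            z = (abs(w_small - mean_w) - 0.5) / math.sqrt(var_w)
            p_value = float(2.0 * norm.sf(max(z, 0.0)))
        reject = p_value <= significance

    return RankSumResult(
        n1=n1,
        n2=n2,
        w1=w1,
        w2=w2,
        decision="reject" if reject else "accept",
        significance=significance,
        confidence_level=(1.0 - significance) * 100.0,
        p_value=p_value,
        critical_value=critical_value,
        method=method,
    )


def summarize_runs(per_run_metrics, times=None) -> dict:
    """Mean/best/worst/sample-std per metric over repeated runs.

    ``per_run_metrics`` is a list of :class:`MetricsReport` (or dicts);
    a single run reports std 0 with ``degenerate_std=True``.  ``times``
    (seconds per run) contributes a ``mean_time`` field.
    """
    if len(per_run_metrics) == 0:
        raise ValueError("need at least one run")
    rows = [
        m.as_dict() if isinstance(m, MetricsReport) else dict(m)
        for m in per_run_metrics
    ]
    R = len(rows)
    summary: dict = {"n_runs": R, "degenerate_std": R == 1}
    for name in METRIC_NAMES:
        vals = np.array([row[name] for row in rows], dtype=float)
        summary[name] = {
            "mean": float(vals.mean()),
            "best": float(vals.max()),
            "worst": float(vals.min()),
            "std": float(vals.std(ddof=1)) if R > 1 else 0.0,
        }
    if times is not None:
        summary["mean_time"] = float(np.mean(times))
    return summary
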