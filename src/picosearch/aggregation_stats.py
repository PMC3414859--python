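"""Cross-question aggregation and paired strategy comparisons.

Per-question metrics are summarized per strategy with nonparametric
statistics (median and interquartile range, quantiles by linear
interpolation between order statistics), and strategies are compared
pairwise with the Wilcoxon signed-rank test on within-question
differences.

The Wilcoxon implementation follows the classical form: zero
differences are dropped, absolute differences are ranked with average
ranks for ties, and the statistic is the smaller of the positive- and
negative-rank sums. For 12 or fewer nonzero differences the two-sided
p-value is exact, computed from the full sign-flip distribution (a
count recursion over the doubled ranks, so tied half-integer ranks stay
integral); above that, a normal approximation with tie-corrected
variance and a 0.5 continuity correction is used. No multiple-testing
adjustment is applied; comparisons report raw paired p-values.

Increased/stable/decreased counts between two strategies are taken on
the reported one-decimal scale, so questions whose values agree at
reporting precision count as stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from picosearch.retrieval_metrics import (
    GoldStandard,
    MetricResult,
    RankedOutput,
    cumulative_curve,
    nnr,
    round_half_away,
)

__all__ = [
    "StrategySummary",
    "ComparisonReport",
    "WilcoxonResult",
    "median_iqr",
    "wilcoxon_signed_rank",
    "compare_strategies",
    "summarize_strategy",
    "median_cumulative_curve",
    "EXACT_THRESHOLD",
]

#: Largest number of nonzero paired differences for which the exact
#: sign-flip distribution is used (2^12 = 4096 assignments).
EXACT_THRESHOLD = 12


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles (Q1, Q3) by linear interpolation.

    Uses the convention where quantile p sits at position 1 + p(n - 1)
    in the sorted sample (numpy's default "linear" method).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires a non-empty list")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(med), float(q1), float(q3)


class WilcoxonResult(NamedTuple):
    statistic: float
    p_two_sided: float
    n_effective: int
    method: str            # "exact" | "normal" | "degenerate"


def _exact_sign_flip_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all 2^n sign assignments of the given ranks.

    Works on doubled ranks so average ranks for ties remain integers:
    the count of assignments reaching each positive-rank sum is built
    by the usual polynomial-coefficient recursion.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total2 = int(r2.sum())
    counts = np.zeros(total2 + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total2 + 1 - r]
        counts = counts + shifted
    n_assign = 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    w_small2 = min(w2, total2 - w2)
    p = (counts[: w_small2 + 1].sum()
         + counts[total2 - w_small2:].sum()) / n_assign
    return min(1.0, float(p))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float],
    exact_threshold: int = EXACT_THRESHOLD,
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test of y against x.

    Zero differences are dropped (classical treatment; the alternative
    Pratt method, which keeps zeros in the ranking, is not used).
    Returns the smaller of the positive- and negative-rank sums, the
    two-sided p-value, and the number of nonzero differences.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if xa.size < 2:
        raise ValueError("need at least 2 pairs")
    d = ya - xa
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if n <= exact_threshold:
        p = _exact_sign_flip_p(ranks, w_plus)
        return WilcoxonResult(statistic, p, n, "exact")
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    if var <= 0:       # all |d| identical and n small enough to degenerate
        return WilcoxonResult(statistic, 1.0, n, "normal")
    z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    return WilcoxonResult(statistic, p, n, "normal")


@dataclass(frozen=True)
class StrategySummary:
    """Median/IQR aggregates of one strategy over a set of questions."""

    strategy_id: str
    n_questions: int
    hits_median: float
    hits_iqr: tuple[float, float]
    sens_median: float
    sens_iqr: tuple[float, float]
    ppv_median: float
    ppv_iqr: tuple[float, float]
    nnr_median: int | None


def summarize_strategy(
    strategy_id: str,
    metrics: Sequence[MetricResult],
    output_sizes: Sequence[int] | None = None,
) -> StrategySummary:
    """Collapse per-question metrics into one summary row.

    ``output_sizes`` are the full output sizes (hit counts) per
    question; when omitted, ``n_screened`` of each metric is used,
    which coincides with the hit count for full-output metrics.
    The median NNR is derived from the median PPV (nearest-integer
    reciprocal), mirroring how summary tables report it.
    """
    if not metrics:
        raise ValueError("summarize_strategy requires at least one question")
    sizes = ([m.n_screened for m in metrics] if output_sizes is None
             else list(output_sizes))
    hits_med, hits_q1, hits_q3 = median_iqr(sizes)
    sens_med, sens_q1, sens_q3 = median_iqr([m.sensitivity_pct for m in metrics])
    ppv_med, ppv_q1, ppv_q3 = median_iqr([m.ppv_pct for m in metrics])
    sens_med = round_half_away(sens_med, 1)
    ppv_med = round_half_away(ppv_med, 1)
    return StrategySummary(
        strategy_id=strategy_id,
        n_questions=len(metrics),
        hits_median=hits_med,
        hits_iqr=(hits_q1, hits_q3),
        sens_median=sens_med,
        sens_iqr=(round_half_away(sens_q1, 1), round_half_away(sens_q3, 1)),
        ppv_median=ppv_med,
        ppv_iqr=(round_half_away(ppv_q1, 1), round_half_away(ppv_q3, 1)),
        nnr_median=nnr(ppv_med / 100.0) if ppv_med > 0 else None,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Paired comparison of strategy b against strategy a across questions."""

    strategy_a: str
    strategy_b: str
    measure: str
    n_increased: int
    n_stable: int
    n_decreased: int
    zero_yield_a: int
    zero_yield_b: int
    wilcoxon_statistic: float
    p_two_sided: float
    n_effective: int


def compare_strategies(
    metrics_a: Sequence[MetricResult],
    metrics_b: Sequence[MetricResult],
    measure: Literal["sensitivity", "ppv"] = "sensitivity",
) -> ComparisonReport:
    """Question-by-question comparison of one measure between two strategies.

    Both lists must cover the same questions at the same cutoff. Values
    are compared on the reported one-decimal scale; zero-yield counts
    are questions with no relevant article within the cutoff.
    """
    by_q_a = {m.question_id: m for m in metrics_a}
    by_q_b = {m.question_id: m for m in metrics_b}
    if set(by_q_a) != set(by_q_b) or len(by_q_a) != len(metrics_a):
        raise ValueError("the two metric lists must cover the same questions")
    cutoffs = {m.cutoff for m in metrics_a} | {m.cutoff for m in metrics_b}
    if len(cutoffs) != 1:
        raise ValueError("all metrics must share one cutoff")
    attr = "sensitivity_pct" if measure == "sensitivity" else "ppv_pct"
    questions = sorted(by_q_a)
    va = [getattr(by_q_a[q], attr) for q in questions]
    vb = [getattr(by_q_b[q], attr) for q in questions]
    n_inc = sum(1 for a, b in zip(va, vb) if b > a)
    n_dec = sum(1 for a, b in zip(va, vb) if b < a)
    n_stable = len(questions) - n_inc - n_dec
    wr = wilcoxon_signed_rank(va, vb)
    return ComparisonReport(
        strategy_a=metrics_a[0].strategy_id,
        strategy_b=metrics_b[0].strategy_id,
        measure=measure,
        n_increased=n_inc,
        n_stable=n_stable,
        n_decreased=n_dec,
        zero_yield_a=sum(1 for q in questions
                         if by_q_a[q].n_relevant_retrieved == 0),
        zero_yield_b=sum(1 for q in questions
                         if by_q_b[q].n_relevant_retrieved == 0),
        wilcoxon_statistic=wr.statistic,
        p_two_sided=wr.p_two_sided,
        n_effective=wr.n_effective,
    )


def median_cumulative_curve(
    outputs: Sequence[RankedOutput],
    golds: Sequence[GoldStandard],
    max_rank: int,
) -> list[float]:
    """Median over questions of the cumulative sensitivity curve.

    Element k (1-based) is the median across questions of sensitivity
    after screening k items; it is nondecreasing in k because each
    per-question curve is.
    """
    gold_by_q = {g.question_id: g for g in golds}
    if {o.question_id for o in outputs} != set(gold_by_q):
        raise ValueError("outputs and gold standards must cover the same questions")
    curves = np.array(
        [cumulative_curve(o, gold_by_q[o.question_id], max_rank)
         for o in outputs]
    )
    return [round_half_away(float(v), 1) for v in np.median(curves, axis=0)]
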