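"""Median/IQR, Wilcoxon signed-rank (exact + approximate), comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from picosearch.aggregation_stats import (
    compare_strategies,
    median_cumulative_curve,
    median_iqr,
    summarize_strategy,
    wilcoxon_signed_rank,
)
from picosearch.interface_io import fixture_metric_results
from picosearch.retrieval_metrics import GoldStandard, MetricResult, RankedOutput


def brute_force_wilcoxon_p(d: np.ndarray) -> tuple[float, float]:
    """Enumeration oracle: two-sided p over all sign assignments of |d|."""
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    w_small = min(w_plus, total - w_plus)
    hits = 0
    count = 0
    for signs in itertools.product((-1.0, 1.0), repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s > 0)
        count += 1
        if w <= w_small + 1e-9 or w >= total - w_small - 1e-9:
            hits += 1
    return min(w_plus, total - w_plus), min(1.0, hits / count)


def test_median_iqr_examples():
    assert median_iqr([5]) == (5, 5, 5)
    med, q1, q3 = median_iqr([1, 2, 3, 4])
    assert (med, q1, q3) == (2.5, 1.75, 3.25)   # 1 + p(n-1) positions
    with pytest.raises(ValueError):
        median_iqr([])


@given(st.lists(st.floats(min_value=-100, max_value=100), min_size=1,
                max_size=25))
def test_median_iqr_matches_sort_and_interpolate_oracle(values):
    def quantile(sorted_v, p):
        pos = p * (len(sorted_v) - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, len(sorted_v) - 1)
        return sorted_v[lo] + (pos - lo) * (sorted_v[hi] - sorted_v[lo])

    sv = sorted(values)
    med, q1, q3 = median_iqr(values)
    assert med == pytest.approx(quantile(sv, 0.5))
    assert q1 == pytest.approx(quantile(sv, 0.25))
    assert q3 == pytest.approx(quantile(sv, 0.75))
    assert q1 <= med <= q3


def test_wilcoxon_degenerate_identical_samples():
    r = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (r.statistic, r.p_two_sided, r.n_effective) == (0.0, 1.0, 0)
    assert r.method == "degenerate"


def test_wilcoxon_exact_matches_scipy_without_ties():
    x = [0.0] * 8
    y = [1.0, -2.0, 3.5, 0.25, -5.0, 6.0, 0.75, -4.0]
    ours = wilcoxon_signed_rank(x, y)
    ref = sps.wilcoxon(y, correction=False, method="exact")
    assert ours.method == "exact"
    assert ours.statistic == ref.statistic
    assert ours.p_two_sided == pytest.approx(ref.pvalue)


def test_wilcoxon_normal_branch_matches_scipy_correction():
    rng = np.random.default_rng(7)
    x = rng.normal(size=30)
    y = x + rng.normal(0.4, 1.0, size=30)
    ours = wilcoxon_signed_rank(x, y)
    ref = sps.wilcoxon(y - x, correction=True, method="approx")
    assert ours.method == "normal"
    assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


diff_lists = st.lists(
    st.integers(min_value=-5, max_value=5).map(float), min_size=2, max_size=9
).filter(lambda d: any(v != 0 for v in d))


@settings(max_examples=60)
@given(diff_lists)
def test_wilcoxon_exact_equals_sign_flip_enumeration(diffs):
    """The count-recursion exact branch agrees with brute enumeration,
    including under ties and for both orientations."""
    d = np.asarray(diffs)
    x = np.zeros_like(d)
    r = wilcoxon_signed_rank(x, d)
    stat_oracle, p_oracle = brute_force_wilcoxon_p(d)
    assert r.method == "exact"
    assert r.statistic == stat_oracle
    assert r.p_two_sided == pytest.approx(p_oracle)
    swapped = wilcoxon_signed_rank(d, x)
    assert swapped.p_two_sided == pytest.approx(r.p_two_sided)


@given(diff_lists)
def test_wilcoxon_rank_sums_partition(diffs):
    d = np.asarray(diffs)
    nonzero = d[d != 0]
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = ranks[nonzero > 0].sum()
    r = wilcoxon_signed_rank(np.zeros_like(d), d)
    n = r.n_effective
    assert w_plus + (ranks.sum() - w_plus) == n * (n + 1) / 2
    assert r.statistic == min(w_plus, ranks.sum() - w_plus)


def _metric(qid, sid, sens, n_rel, cutoff=40):
    return MetricResult(qid, sid, cutoff, 10, min(cutoff, 40), n_rel, sens,
                        round(100 * n_rel / 40, 1))


def test_compare_self_is_all_stable():
    ms = [_metric(f"q{i}", "S1", 10.0 * i, i) for i in range(5)]
    rep = compare_strategies(ms, ms)
    assert (rep.n_increased, rep.n_stable, rep.n_decreased) == (0, 5, 0)
    assert rep.p_two_sided == 1.0


def test_compare_counts_are_order_invariant():
    a = [_metric(f"q{i}", "S1", float(i), i) for i in range(6)]
    b = [_metric(f"q{i}", "S4", float(i * 2), i) for i in range(6)]
    rep1 = compare_strategies(a, b)
    rep2 = compare_strategies(list(reversed(a)), b)
    assert (rep1.n_increased, rep1.n_stable, rep1.n_decreased) == (
        rep2.n_increased, rep2.n_stable, rep2.n_decreased)
    assert rep1.p_two_sided == rep2.p_two_sided


def test_compare_rejects_mismatched_questions():
    a = [_metric("q1", "S1", 1.0, 1)]
    b = [_metric("q2", "S4", 1.0, 1)]
    with pytest.raises(ValueError):
        compare_strategies(a, b)


# ---------------------------------------------------------------------------
# Benchmark-fixture aggregation (printed per-question values)

def test_fixture_s1_two_page_medians(table1):
    ms = fixture_metric_results(table1, "S1", "2p")
    s = summarize_strategy("S1", ms)
    assert s.sens_median == 9.8
    assert s.ppv_median == 2.5
    assert s.nnr_median == 40


def test_fixture_s4_two_page_ppv_median(table1):
    s = summarize_strategy("S4", fixture_metric_results(table1, "S4", "2p"))
    assert s.ppv_median == 21.3
    assert s.nnr_median == 5


def test_fixture_narrow_filter_comparison(table1):
    rep = compare_strategies(
        fixture_metric_results(table1, "S1", "2p"),
        fixture_metric_results(table1, "S4", "2p"),
    )
    assert (rep.n_increased, rep.n_stable, rep.n_decreased) == (21, 6, 3)
    assert (rep.zero_yield_a, rep.zero_yield_b) == (11, 4)
    assert rep.p_two_sided < 0.001


def test_single_question_summary_equals_its_values():
    m = _metric("q1", "S1", 50.0, 5)
    s = summarize_strategy("S1", [m])
    assert s.sens_median == 50.0
    assert s.hits_median == m.n_screened


def test_median_cumulative_curve_properties():
    golds, outputs = [], []
    for i in range(4):
        gold_ids = frozenset({f"q{i}a", f"q{i}b"})
        golds.append(GoldStandard(f"q{i}", gold_ids, gold_ids))
        ranked = (f"q{i}x", f"q{i}a", f"q{i}y", f"q{i}b")
        outputs.append(RankedOutput(f"q{i}", "S", ranked))
    curve = median_cumulative_curve(outputs, golds, 6)
    assert curve == [0.0, 50.0, 50.0, 100.0, 100.0, 100.0]
    assert curve == sorted(curve)
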