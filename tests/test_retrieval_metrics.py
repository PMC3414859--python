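"""Sensitivity/PPV/NNR worked examples, cutoffs, and oracle properties."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from picosearch.errors import (
    InvalidCutoffError,
    NotEvaluableError,
    UndefinedNNRError,
)
from picosearch.retrieval_metrics import (
    GoldStandard,
    RankedOutput,
    cumulative_curve,
    evaluate,
    nnr,
    round_half_away,
    zero_yield,
)


def make_case(n_gold: int, gold_in_output: int, n_output: int,
              gold_positions: list[int] | None = None):
    """Gold of n_gold indexed ids; output of n_output ids containing
    gold_in_output of them (at given 0-based positions, default first)."""
    gold_ids = [f"g{i}" for i in range(n_gold)]
    fill = iter(f"x{i}" for i in range(n_output))
    positions = (gold_positions if gold_positions is not None
                 else list(range(gold_in_output)))
    ranked = [next(fill) for _ in range(n_output)]
    for pos, g in zip(positions, gold_ids):
        ranked[pos] = g
    gold = GoldStandard("q", frozenset(gold_ids), frozenset(gold_ids))
    return RankedOutput("q", "S", tuple(ranked)), gold


def test_full_output_worked_example():
    """9-item output holding 6 of 7 gold: sensitivity 85.7, PPV 66.7."""
    output, gold = make_case(7, 6, 9)
    m = evaluate(output, gold, "full")
    assert (m.sensitivity_pct, m.ppv_pct) == (85.7, 66.7)
    assert (m.n_relevant_retrieved, m.n_screened) == (6, 9)


def test_two_page_cutoff_truncates_denominator():
    """43-item output, all 8 gold in the top 40: PPV 8/40 = 20.0 at the
    2-page cutoff, 8/43 = 18.6 on the full output."""
    output, gold = make_case(8, 8, 43)
    at40 = evaluate(output, gold, 40)
    assert (at40.sensitivity_pct, at40.ppv_pct) == (100.0, 20.0)
    full = evaluate(output, gold, "full")
    assert full.ppv_pct == 18.6
    assert round_half_away(100 * 8 / 43, 1) == 18.6


def test_ppv_denominator_is_min_cutoff_output_length():
    """12-item output screened 'to 40' still shows only 12 items."""
    output, gold = make_case(4, 4, 12)
    m = evaluate(output, gold, 40)
    assert m.n_screened == 12
    assert m.ppv_pct == 33.3
    assert evaluate(output, gold, "full").ppv_pct == 33.3


def test_disjoint_output_scores_zero():
    gold = GoldStandard("q", frozenset({"a", "b"}), frozenset({"a", "b"}))
    output = RankedOutput("q", "S", ("x", "y"))
    m = evaluate(output, gold)
    assert (m.sensitivity_pct, m.ppv_pct) == (0.0, 0.0)
    assert not m.degenerate


def test_empty_output_is_degenerate_not_error():
    gold = GoldStandard("q", frozenset({"a"}), frozenset({"a"}))
    m = evaluate(RankedOutput("q", "S", ()), gold)
    assert m.degenerate and m.ppv_pct == 0.0


def test_error_conditions():
    gold_empty = GoldStandard("q", frozenset({"a"}), frozenset())
    output = RankedOutput("q", "S", ("a",))
    with pytest.raises(NotEvaluableError):
        evaluate(output, gold_empty)
    gold = GoldStandard("q", frozenset({"a"}), frozenset({"a"}))
    with pytest.raises(InvalidCutoffError):
        evaluate(output, gold, 0)
    with pytest.raises(InvalidCutoffError):
        evaluate(output, gold, -3)


def test_duplicates_deduplicated_keeping_best_rank():
    gold = GoldStandard("q", frozenset({"a"}), frozenset({"a"}))
    output = RankedOutput("q", "S", ("x", "a", "x", "a", "y"))
    assert output.ranked_ids == ("x", "a", "y")
    assert evaluate(output, gold).n_screened == 3


def test_identifiers_are_opaque_strings():
    """Leading zeros distinguish identifiers (PMIDs are not integers)."""
    gold = GoldStandard("q", frozenset({"007"}), frozenset({"007"}))
    assert evaluate(RankedOutput("q", "S", ("7",)), gold).n_relevant_retrieved == 0
    assert evaluate(RankedOutput("q", "S", (" 007 ",)), gold).n_relevant_retrieved == 1


@pytest.mark.parametrize(
    "ppv, expected", [(0.025, 40), (0.321, 3), (1.0, 1), (0.213, 5), (0.5, 2)]
)
def test_nnr_reciprocal(ppv, expected):
    assert nnr(ppv) == expected


def test_nnr_undefined_at_zero():
    with pytest.raises(UndefinedNNRError):
        nnr(0.0)


def test_cumulative_curve_direct_count():
    gold = GoldStandard("q", frozenset({"a", "b"}), frozenset({"a", "b"}))
    output = RankedOutput("q", "S", ("x", "a", "y", "b"))
    assert cumulative_curve(output, gold, 4) == [0.0, 50.0, 50.0, 100.0]
    # flat at full-output sensitivity beyond the end of the output
    assert cumulative_curve(output, gold, 6)[4:] == [100.0, 100.0]


def test_zero_yield_cases():
    gold = GoldStandard("q", frozenset({"a"}), frozenset({"a"}))
    assert not zero_yield(RankedOutput("q", "S", ("a", "x")), gold, 40)
    late = tuple(f"x{i}" for i in range(50)) + ("a",)
    assert zero_yield(RankedOutput("q", "S", late), gold, 40)


ids = st.integers(min_value=0, max_value=30).map(str)
instances = st.tuples(
    st.sets(ids, min_size=1, max_size=10),          # indexed gold
    st.lists(ids, max_size=40, unique=True),        # ranked output
    st.integers(min_value=1, max_value=50),         # cutoff
)


@given(instances)
def test_counts_match_brute_force_intersection(case):
    gold_ids, ranked, cutoff = case
    gold = GoldStandard("q", frozenset(gold_ids), frozenset(gold_ids))
    output = RankedOutput("q", "S", tuple(ranked))
    m = evaluate(output, gold, cutoff)
    screened = ranked[:cutoff]
    assert m.n_relevant_retrieved == len(set(screened) & gold_ids)
    assert m.n_screened == min(cutoff, len(ranked))
    assert m.n_relevant_retrieved <= min(m.gold_size, m.n_screened)


@given(instances)
def test_sensitivity_monotone_and_curve_consistent(case):
    gold_ids, ranked, cutoff = case
    gold = GoldStandard("q", frozenset(gold_ids), frozenset(gold_ids))
    output = RankedOutput("q", "S", tuple(ranked))
    curve = cumulative_curve(output, gold, 50)
    assert curve == sorted(curve)  # nondecreasing
    full = evaluate(output, gold, "full").sensitivity_pct
    assert curve[-1] == full      # supremum reached by rank 50 >= |output|
    assert curve[cutoff - 1] == evaluate(output, gold, cutoff).sensitivity_pct
    # beyond the output length, cutoff metrics equal full-output metrics
    big = evaluate(output, gold, len(ranked) + 1 if ranked else 1)
    assert (big.sensitivity_pct, big.ppv_pct) == (
        full, evaluate(output, gold, "full").ppv_pct)
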