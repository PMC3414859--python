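"""Retrieval performance of one ranked search output against one gold standard.

The gold standard for a clinical question is the set of trials included
in a systematic review on that question, restricted to those indexed in
PubMed (a study absent from PubMed cannot be retrieved by any search
strategy, so it is excluded from the sensitivity denominator).

Two measures are computed, at a screening cutoff or over the full
output:

- **sensitivity** (recall): the proportion of gold-standard articles
  present in the screened portion of the output;
- **positive predictive value** (PPV, precision): the proportion of
  screened items that belong to the gold standard. At a cutoff the
  denominator is the number *actually* screened, ``min(cutoff,
  output length)`` — a 12-item output screened "to 40" still only shows
  12 items.

The default cutoff of interest in this package is 40 items — two pages
of PubMed output, a realistic screening budget at the point of care.
The **number needed to read** (NNR) is the reciprocal of PPV: the
average number of items a reader must screen to find one relevant
article.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from picosearch.errors import (
    InvalidCutoffError,
    NotEvaluableError,
    UndefinedNNRError,
)

__all__ = [
    "GoldStandard",
    "RankedOutput",
    "MetricResult",
    "evaluate",
    "nnr",
    "cumulative_curve",
    "zero_yield",
    "round_half_away",
    "TWO_PAGE_CUTOFF",
]

#: Two pages of PubMed output, the conventional point-of-care screening budget.
TWO_PAGE_CUTOFF = 40

Cutoff = int | Literal["full"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (so 21.25 -> 21.3, -0.5 -> -1).

    Percentages are reported to one decimal with this rule; internal
    arithmetic keeps full precision.
    """
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor


@dataclass(frozen=True)
class GoldStandard:
    """A question's included studies and its PubMed-indexed subset.

    ``indexed_ids`` (a subset of ``included_ids``) is the evaluation
    denominator; identifiers are opaque strings compared after trimming,
    never parsed as integers (PMID leading zeros are preserved).
    """

    question_id: str
    included_ids: frozenset[str]
    indexed_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "included_ids", frozenset(s.strip() for s in self.included_ids)
        )
        object.__setattr__(
            self, "indexed_ids", frozenset(s.strip() for s in self.indexed_ids)
        )
        if not self.indexed_ids <= self.included_ids:
            raise ValueError(
                f"question {self.question_id!r}: indexed_ids must be a subset "
                "of included_ids"
            )

    @property
    def gold_size(self) -> int:
        return len(self.indexed_ids)


@dataclass(frozen=True)
class RankedOutput:
    """An ordered, deduplicated list of article identifiers from one search.

    Rank 1 is the first item on page 1. Duplicates in the raw input are
    dropped keeping the first (best) rank; PubMed outputs are
    duplicate-free but files prepared by hand may not be.
    """

    question_id: str
    strategy_id: str
    ranked_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for raw in self.ranked_ids:
            article = raw.strip()
            if article not in seen:
                seen[article] = None
        object.__setattr__(self, "ranked_ids", tuple(seen))

    def __len__(self) -> int:
        return len(self.ranked_ids)


@dataclass(frozen=True)
class MetricResult:
    """Sensitivity/PPV of one search at one cutoff, percentages to 1 decimal.

    ``degenerate`` marks a PPV reported as 0.0 because nothing was
    screened (empty output), rather than because screened items were
    all irrelevant.
    """

    question_id: str
    strategy_id: str
    cutoff: Cutoff
    gold_size: int
    n_screened: int
    n_relevant_retrieved: int
    sensitivity_pct: float
    ppv_pct: float
    degenerate: bool = False

    @property
    def nnr(self) -> int | None:
        """Number needed to read, or None when PPV is zero."""
        if self.ppv_pct <= 0:
            return None
        return nnr(self.n_relevant_retrieved / self.n_screened)


def _check_cutoff(cutoff: Cutoff) -> None:
    if cutoff == "full":
        return
    if not isinstance(cutoff, int) or isinstance(cutoff, bool) or cutoff <= 0:
        raise InvalidCutoffError(
            f"cutoff must be a positive integer or 'full', got {cutoff!r}"
        )


def evaluate(output: RankedOutput, gold: GoldStandard,
             cutoff: Cutoff = "full") -> MetricResult:
    """Score one ranked output against one gold standard at a cutoff.

    The screened set is the first ``min(cutoff, len(output))`` items
    (all of them for ``cutoff="full"``). Sensitivity is over the
    indexed gold set; PPV is over the screened count.
    """
    _check_cutoff(cutoff)
    if gold.gold_size == 0:
        raise NotEvaluableError(
            f"question {gold.question_id!r}: no PubMed-indexed gold article; "
            "no search can be evaluated against it"
        )
    if cutoff == "full":
        screened = output.ranked_ids
    else:
        screened = output.ranked_ids[:cutoff]
    n_screened = len(screened)
    n_relevant = sum(1 for a in screened if a in gold.indexed_ids)
    sensitivity = 100.0 * n_relevant / gold.gold_size
    if n_screened > 0:
        ppv = 100.0 * n_relevant / n_screened
        degenerate = False
    else:
        ppv = 0.0
        degenerate = True
    return MetricResult(
        question_id=gold.question_id,
        strategy_id=output.strategy_id,
        cutoff=cutoff,
        gold_size=gold.gold_size,
        n_screened=n_screened,
        n_relevant_retrieved=n_relevant,
        sensitivity_pct=round_half_away(sensitivity, 1),
        ppv_pct=round_half_away(ppv, 1),
        degenerate=degenerate,
    )


def nnr(ppv_fraction: float) -> int:
    """Number needed to read: nearest-integer reciprocal of a PPV fraction.

    >>> nnr(0.025)
    40
    >>> nnr(0.321)
    3
    """
    if not 0.0 < ppv_fraction <= 1.0:
        if ppv_fraction == 0:
            raise UndefinedNNRError(
                "PPV is zero: no relevant article in the screened output"
            )
        raise ValueError(f"PPV fraction must lie in (0, 1], got {ppv_fraction!r}")
    return int(round_half_away(1.0 / ppv_fraction))


def cumulative_curve(output: RankedOutput, gold: GoldStandard,
                     max_rank: int) -> list[float]:
    """Sensitivity (to 1 decimal) after screening k = 1..max_rank items.

    Beyond the end of the output the curve stays flat at the
    full-output sensitivity. The curve is nondecreasing in k.
    """
    _check_cutoff(max_rank)
    if gold.gold_size == 0:
        raise NotEvaluableError(
            f"question {gold.question_id!r}: no PubMed-indexed gold article"
        )
    curve: list[float] = []
    n_relevant = 0
    for k in range(1, max_rank + 1):
        if k <= len(output.ranked_ids):
            if output.ranked_ids[k - 1] in gold.indexed_ids:
                n_relevant += 1
        curve.append(round_half_away(100.0 * n_relevant / gold.gold_size, 1))
    return curve


def zero_yield(output: RankedOutput, gold: GoldStandard, cutoff: int) -> bool:
    """True iff the screened portion contains no gold-standard article."""
    return evaluate(output, gold, cutoff).n_relevant_retrieved == 0
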