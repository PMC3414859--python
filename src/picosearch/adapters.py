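"""Pluggable sources of ranked search outputs.

The pipeline consumes :class:`~picosearch.retrieval_metrics.RankedOutput`
objects and does not care where they come from. A *search adapter* maps
(question, strategy, date cap) to a ranked output. Two implementations
ship here:

- :class:`StaticAdapter`, which serves pre-loaded outputs (from files
  or a simulation) — the only adapter used in tests;
- a documented contract for a live PubMed E-utilities adapter, which is
  intentionally **not** implemented: live searches are irreproducible
  (the database changes daily) and need network access, so they sit
  outside the tested surface. Anyone wiring one up only has to satisfy
  :class:`SearchAdapter`.
"""

from __future__ import annotations

import datetime
from typing import Protocol

from picosearch.query_builder import PicoQuestion, SearchStrategy
from picosearch.retrieval_metrics import RankedOutput

__all__ = ["SearchAdapter", "StaticAdapter"]


class SearchAdapter(Protocol):
    """Contract: produce the ranked output of one strategy for one question.

    Implementations must return an output whose ``question_id`` matches
    the question and whose identifiers are already restricted to
    publications up to ``date_cap`` (the evaluator carries no dates).
    """

    def fetch(self, question: PicoQuestion, strategy: SearchStrategy,
              date_cap: datetime.date | None = None) -> RankedOutput:
        ...


class StaticAdapter:
    """Serve outputs from a pre-loaded (question, strategy) table."""

    def __init__(self, outputs: list[RankedOutput]):
        self._table = {(o.question_id, o.strategy_id): o for o in outputs}

    def fetch(self, question: PicoQuestion, strategy: SearchStrategy,
              date_cap: datetime.date | None = None) -> RankedOutput:
        try:
            return self._table[(question.question_id, strategy.strategy_id)]
        except KeyError:
            raise KeyError(
                f"no stored output for ({question.question_id!r}, "
                f"{strategy.strategy_id!r})"
            ) from None
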