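"""PICO Boolean query construction and the 15-strategy search grid.

A clinical question structured by the PICO framework (population,
interventions, comparison, outcomes) is turned into a PubMed-dialect
Boolean query: terms are OR-ed within each category (to gain
sensitivity), multiword terms are wrapped in parentheses rather than
quotes (so PubMed's automatic term mapping still applies), and the
category clauses are AND-ed together (so every retrieved citation
matches all elements of the question). A *PIC* query drops the outcomes
clause; a question whose comparison shares its terms with the
intervention simply carries an empty comparison list, which is silently
omitted.

The strategy grid crosses the query form with PubMed's Clinical Queries
therapy filters (broad = sensitivity-maximizing, narrow =
specificity-maximizing), language/species limits and the Abridged Index
Medicus (AIM) core-journal subset, plus three related-articles searches
seeded from the top-ranked citations of a narrow-filtered search.
Related-articles strategies have no query text of their own — PubMed's
similarity ranking is opaque — so their outputs are supplied externally
or simulated.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field

from picosearch.errors import (
    InvalidQuestionError,
    InvalidTermError,
    UnsupportedStrategyError,
)

__all__ = [
    "PicoQuestion",
    "SearchStrategy",
    "QueryString",
    "FilterConfig",
    "build_category_clause",
    "compose_query",
    "render_strategy_query",
    "strategy_grid",
    "DEFAULT_FILTER_CONFIG",
]

#: Query forms.
PIC = "PIC"
PICO = "PICO"
RELATED = "RELATED"

_WS = re.compile(r"\s+")


def _normalize_term(term: str) -> str:
    """Collapse runs of whitespace and trim; raise on blank terms."""
    if not isinstance(term, str) or not term.strip():
        raise InvalidTermError(f"blank or all-whitespace search term: {term!r}")
    return _WS.sub(" ", term.strip())


@dataclass(frozen=True)
class PicoQuestion:
    """A clinical question structured into the four PICO categories.

    ``population_terms`` and ``intervention_terms`` must be non-empty;
    ``comparison_terms`` may be empty (for about half of real therapy
    questions the comparison shares its wording with the intervention
    and no separate term is retained).
    """

    question_id: str
    population_terms: tuple[str, ...]
    intervention_terms: tuple[str, ...]
    comparison_terms: tuple[str, ...] = ()
    outcome_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("population_terms", "intervention_terms",
                     "comparison_terms", "outcome_terms"):
            terms = tuple(_normalize_term(t) for t in getattr(self, name))
            object.__setattr__(self, name, terms)
        if not self.population_terms or not self.intervention_terms:
            raise InvalidQuestionError(
                f"question {self.question_id!r}: population and intervention "
                "term lists must be non-empty"
            )


@dataclass(frozen=True)
class SearchStrategy:
    """One cell of the strategy grid: query form + filter + limits.

    ``related_seed_rank`` is the 1-based rank (within the seeding
    search's output) of the citation whose related-articles list this
    strategy screens; it is present exactly for RELATED strategies.
    """

    strategy_id: str
    query_form: str                       # PIC | PICO | RELATED
    cq_filter: str = "none"               # none | therapy_broad | therapy_narrow
    limits: frozenset[str] = frozenset()  # subset of {english, human, aim}
    related_seed_rank: int | None = None

    def __post_init__(self) -> None:
        if self.query_form not in (PIC, PICO, RELATED):
            raise ValueError(f"unknown query form {self.query_form!r}")
        if self.cq_filter not in ("none", "therapy_broad", "therapy_narrow"):
            raise ValueError(f"unknown filter {self.cq_filter!r}")
        if not self.limits <= {"english", "human", "aim"}:
            raise ValueError(f"unknown limits {set(self.limits)!r}")
        if (self.related_seed_rank is not None) != (self.query_form == RELATED):
            raise ValueError(
                "related_seed_rank must be present iff query_form is RELATED"
            )
        if self.query_form == RELATED and (
            self.cq_filter != "none" or self.limits
        ):
            raise ValueError("related-articles strategies take no filter or limits")
        if "aim" in self.limits and not {"english", "human"} <= self.limits:
            raise ValueError("the AIM limit is only used on top of english+human")


@dataclass(frozen=True)
class QueryString:
    """A rendered PubMed query plus the form it was built from."""

    text: str
    form: str
    date_cap: datetime.date | None = None


@dataclass(frozen=True)
class FilterConfig:
    """Editable texts for the Clinical Queries therapy filters and limits.

    Defaults are the 2005 Haynes therapy filters as shipped in PubMed's
    Clinical Queries, and PubMed's standard limit expansions. Filter
    strings drift over time, so they live in configuration rather than
    being hard-wired into the renderer.
    """

    therapy_narrow: str = (
        "randomized controlled trial[Publication Type] OR "
        "(randomized[Title/Abstract] AND controlled[Title/Abstract] "
        "AND trial[Title/Abstract])"
    )
    therapy_broad: str = (
        "(clinical[Title/Abstract] AND trial[Title/Abstract]) OR "
        "clinical trials as topic[MeSH Terms] OR "
        "clinical trial[Publication Type] OR random*[Title/Abstract] OR "
        "random allocation[MeSH Terms] OR therapeutic use[MeSH Subheading]"
    )
    english: str = "English[lang]"
    human: str = "humans[MeSH Terms]"
    aim: str = "jsubsetaim"

    def clause_for(self, key: str) -> str:
        return getattr(self, key)


DEFAULT_FILTER_CONFIG = FilterConfig()

#: Fixed rendering order for limit clauses.
_LIMIT_ORDER = ("english", "human", "aim")


def build_category_clause(terms: list[str] | tuple[str, ...]) -> str:
    """Combine the terms of one PICO category into an OR clause.

    Empty list -> empty string (the category is omitted from the query).
    A single term appears bare, parenthesized only if it is multiword.
    Multiple terms: each multiword term parenthesized, joined by
    ``" OR "``, the whole clause wrapped in one outer pair of
    parentheses. Terms are never quoted, so PubMed's automatic term
    mapping applies to each word group.

    >>> build_category_clause(["chronic bronchitis", "COPD"])
    '((chronic bronchitis) OR COPD)'
    >>> build_category_clause(["mucolytics"])
    'mucolytics'
    """
    normalized = [_normalize_term(t) for t in terms]
    if not normalized:
        return ""

    def wrap(term: str) -> str:
        return f"({term})" if " " in term else term

    if len(normalized) == 1:
        return wrap(normalized[0])
    return "(" + " OR ".join(wrap(t) for t in normalized) + ")"


def compose_query(question: PicoQuestion, form: str = PICO) -> QueryString:
    """AND the non-empty category clauses together, in P, I, C, O order.

    ``form=PIC`` drops the outcomes clause; an empty comparison clause
    is silently omitted in either form.
    """
    if form not in (PIC, PICO):
        raise ValueError(f"form must be PIC or PICO, got {form!r}")
    categories = [
        question.population_terms,
        question.intervention_terms,
        question.comparison_terms,
    ]
    if form == PICO:
        categories.append(question.outcome_terms)
    clauses = [c for c in (build_category_clause(t) for t in categories) if c]
    return QueryString(text=" AND ".join(clauses), form=form)


def render_strategy_query(
    base: QueryString,
    strategy: SearchStrategy,
    filter_config: FilterConfig = DEFAULT_FILTER_CONFIG,
) -> QueryString:
    """AND-conjoin a base PIC/PICO query with a strategy's filter and limits.

    Each appended clause (filter, limit, publication-date cap) is
    wrapped in its own pair of parentheses. The date cap renders as a
    publication-date range from 1900/01/01 up to the cap, matching how
    a searcher would restrict PubMed to the period a review covers.
    """
    if strategy.query_form == RELATED:
        raise UnsupportedStrategyError(
            f"{strategy.strategy_id}: related-articles searches have no query "
            "text; their ranked outputs are supplied externally or simulated"
        )
    if strategy.query_form != base.form:
        raise ValueError(
            f"strategy {strategy.strategy_id} expects a {strategy.query_form} "
            f"query but the base query has form {base.form}"
        )
    parts = [base.text]
    if strategy.cq_filter != "none":
        parts.append(f"({filter_config.clause_for(strategy.cq_filter)})")
    for limit in _LIMIT_ORDER:
        if limit in strategy.limits:
            parts.append(f"({filter_config.clause_for(limit)})")
    if base.date_cap is not None:
        cap = base.date_cap.strftime("%Y/%m/%d")
        parts.append(f"(1900/01/01[dp] : {cap}[dp])")
    return QueryString(text=" AND ".join(parts), form=base.form,
                       date_cap=base.date_cap)


def strategy_grid() -> list[SearchStrategy]:
    """The 15 evaluated strategies.

    S1-S5 use the truncated PIC query, S6-S12 the full PICO query,
    crossed with no filter / broad therapy filter / narrow therapy
    filter and with English+human (and, for broad/narrow PICO, the AIM
    core-journal subset) limits. S13-S15 screen the related-articles
    lists of the top 3 citations from the narrow-filtered, limited PICO
    search (S11).
    """
    eh = frozenset({"english", "human"})
    eha = frozenset({"english", "human", "aim"})
    return [
        SearchStrategy("S1", PIC),
        SearchStrategy("S2", PIC, "therapy_broad"),
        SearchStrategy("S3", PIC, "therapy_broad", eh),
        SearchStrategy("S4", PIC, "therapy_narrow"),
        SearchStrategy("S5", PIC, "therapy_narrow", eh),
        SearchStrategy("S6", PICO),
        SearchStrategy("S7", PICO, "therapy_broad"),
        SearchStrategy("S8", PICO, "therapy_broad", eh),
        SearchStrategy("S9", PICO, "therapy_broad", eha),
        SearchStrategy("S10", PICO, "therapy_narrow"),
        SearchStrategy("S11", PICO, "therapy_narrow", eh),
        SearchStrategy("S12", PICO, "therapy_narrow", eha),
        SearchStrategy("S13", RELATED, related_seed_rank=1),
        SearchStrategy("S14", RELATED, related_seed_rank=2),
        SearchStrategy("S15", RELATED, related_seed_rank=3),
    ]
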