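"""Build PubMed Boolean queries from a structured PICO question.

The question below asks about oral mucolytic agents for stable chronic
bronchitis / COPD. Terms are OR-ed within each PICO category (multiword
terms in parentheses, never quotes, so PubMed's automatic term mapping
still applies) and the categories are AND-ed together. The strategy
grid then appends Clinical Queries therapy filters and limits.
"""

from picosearch import PicoQuestion, compose_query, render_strategy_query, strategy_grid

question = PicoQuestion(
    question_id="mucolytics-copd",
    population_terms=("chronic bronchitis", "COPD"),
    intervention_terms=("mucolytics",),
    comparison_terms=("placebo",),
    outcome_terms=("exacerbations",),
)

for form in ("PICO", "PIC"):
    print(f"{form:>4}: {compose_query(question, form).text}")

print()
for strategy in strategy_grid():
    if strategy.query_form == "RELATED":
        print(f"{strategy.strategy_id}: (related-articles search, "
              f"seed rank {strategy.related_seed_rank}; no query text)")
        continue
    base = compose_query(question, strategy.query_form)
    print(f"{strategy.strategy_id}: {render_strategy_query(base, strategy).text}")

# The first two lines are the full PICO query and its truncated PIC form
# (outcomes dropped); the numbered lines show how each strategy AND-appends
# its filter and limit clauses to the base query.
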