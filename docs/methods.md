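# Methods

## Evaluation model

A *question* is a clinical therapy question backed by a systematic
review. The review's included trials, restricted to those indexed in
PubMed, form the gold standard `G`; trials outside PubMed are excluded
from the denominator because no PubMed search can retrieve them. A
*search* is one (question, strategy) pair producing an ordered,
duplicate-free list of article identifiers; identifiers are opaque
strings compared after trimming (PMIDs keep leading zeros).

At a screening cutoff `c` (default 40 items — two PubMed result pages,
the realistic point-of-care budget), the screened set `S` is the first
`min(c, |output|)` items:

- sensitivity = `100 * |S ∩ G| / |G|`
- PPV = `100 * |S ∩ G| / |S|` — the denominator is what was actually
  screened; a 12-item output evaluated "at 40" divides by 12. An empty
  output reports PPV 0.0 with a `degenerate` flag rather than raising:
  real searches can return no hits, and flagging beats inventing a
  number. (How zero-hit searches should report PPV is genuinely
  underdetermined; the flag convention is this package's choice.)
- NNR = `round(1 / PPV)` with ties away from zero; undefined (an
  exception) at PPV 0.

Percentages are rounded to one decimal, half away from zero, **only at
reporting**; internal arithmetic keeps full precision. Cumulative
sensitivity curves evaluate sensitivity at every rank `1..k` and stay
flat at the full-output value beyond the end of the output, so they are
nondecreasing with the full-output sensitivity as supremum.

## Query grammar

Within a PICO category, terms are OR-ed; multiword terms are wrapped in
parentheses rather than quotes so PubMed's automatic term mapping still
expands each word group; a multi-term clause gets one outer pair of
parentheses. Categories are AND-ed in P, I, C, O order; the PIC form
drops outcomes; an empty comparison is omitted silently. Term order
preserves input order and runs of whitespace are collapsed; hyphenated
single tokens are not parenthesized (only actual whitespace triggers
wrapping).

Strategy rendering AND-appends, each in its own parentheses: the
configured Clinical Queries therapy filter, then limits in the fixed
order English → humans → AIM, then an optional publication-date range
(`1900/01/01` up to the cap — the cap models restricting a search to
the period its reference review covers). Filter and limit texts are
configuration, not constants: the defaults are the 2005 Haynes therapy
filters and PubMed's standard limit expansions (`English[lang]`,
`humans[MeSH Terms]`, `jsubsetaim`), but these strings drift over time,
so `FilterConfig` keeps them editable without touching code.

Related-articles strategies (S13–S15) have no query text; PubMed's
similarity ranking is proprietary, so their outputs enter the pipeline
as externally supplied files or simulator presets, and asking the
renderer for them raises.

## Aggregation and inference

Quantiles use linear interpolation between order statistics (the
`1 + p(n−1)` positional convention; numpy's `"linear"` method). This
convention reproduces the benchmark's printed medians and IQRs and is
therefore fixed.

The paired Wilcoxon signed-rank test drops zero differences (classical
treatment; the Pratt variant that ranks zeros is deliberately not
used), ranks `|d|` with average ranks for ties, and takes the smaller
of the positive- and negative-rank sums. With `n ≤ 12` nonzero
differences the two-sided p-value is exact, from the full sign-flip
distribution computed by a count recursion over doubled ranks (doubling
keeps tied average ranks integral); 2^12 assignments is the point past
which exactness stops paying for itself at this study size, and above
it a normal approximation is used with tie-corrected variance
`n(n+1)(2n+1)/24 − Σ(t³−t)/48` and a 0.5 continuity correction. No
multiple-testing adjustment is applied; comparisons report raw paired
p-values.

Improved/stable/decreased counts between two strategies compare values
on the reported one-decimal scale, so differences below reporting
precision count as stable — the convention under which the packaged
benchmark's 21/6/3 split is well defined.

## The packaged benchmark fixture

`data/table1.csv` transcribes a published 30-question benchmark: per
question, the counts of included and PubMed-retrievable trials and the
sensitivity/PPV of an unfiltered PIC search (S1) and its
narrow-filtered counterpart (S4), on the full output and at the
two-page cutoff, exactly as printed (one decimal). The loader checks
the file against an embedded SHA-256 digest and re-derives integer
retrieval counts (`round(sens × |G| / 100)`), verifying each reproduces
the printed percentage; screened counts are recovered from printed PPV
where PPV > 0 (for zero-PPV searches they are unknowable from the
printed figures and are left at the cutoff bound, which no downstream
computation depends on).

One reporting edge of the printed source is left as is: the median of
its 30 per-question narrow-strategy two-page sensitivities is exactly
48.55, which its summary table prints as 48.5 while this package's
half-away-from-zero rule reports 48.6. The discrepancy only arises on
an exact rounding tie; tests and summaries target the cells that are
unambiguous at one decimal, and the fixture is not "corrected" to
force either rendering.

## The simulator

The simulator generates, per question, a gold standard and one ranked
output per configured strategy model:

- **Gold size**: rounded log-normal, floored at 4 (reviews with fewer
  than 4 trials are too thin to serve as gold standards). Default
  log-mean `ln 12`, log-sd 0.70 (fitted once from a median of 12 with
  IQR 7–18); the median simulated size is 12.
- **Indexing**: each included trial is PubMed-indexed independently
  with probability 0.85. If a question draws zero indexed trials
  (probability ≈ 0.15⁴ at the minimum size) one trial is forced
  indexed so the question stays evaluable; the distortion is
  negligible at the default calibration.
- **Retrieval**: an indexed gold trial enters a strategy's output with
  probability `query_retention × filter_retention`. Defaults:
  query retention 0.85 (matching the typical full-output sensitivity
  of unfiltered PIC queries), filter retention 1.0 / 0.99 / 0.93 for
  none / broad / narrow therapy filters.
- **Output size**: the nonrelevant count is a rounded log-normal;
  default medians 173 (unfiltered), 126 (broad), 33 (narrow), 330
  (related), log-sd ≈ 1 fitted from the corresponding IQRs.
- **Rank placement**: relevant items occupy positions drawn without
  replacement with weight `exp(−λu)`, where `u ∈ [0, 1]` is the
  fractional position and `λ = rank_concentration`. `λ = 0` is exactly
  uniform placement; larger λ concentrates relevant items on the first
  pages, the one-parameter mechanism behind the narrow filter's
  two-page advantage. Defaults: λ = 0 (unfiltered), 0.5 (broad), 2
  (narrow), 1 (related) — the simplest values producing the observed
  qualitative ordering, fixed a priori.
- **Related-articles preset**: modeled purely as a large-output,
  moderately concentrated, lower-retention (0.60) source; no content
  similarity is simulated.

Randomness: a single root `SeedSequence` spawns one child stream per
question, so question *i* is byte-identical whether a study holds 3 or
300 questions, and adding questions never perturbs earlier ones.
Realized retention draws are kept in a truth record for
parameter-recovery tests.

**What the simulator does not emulate**: query text or MeSH indexing
(outputs are id lists, not retrieval over documents), per-article
covariates (year, journal), correlation of retention across strategies
beyond the shared indexed gold set, question-level variation in filter
retention (a fixed probability per model), and any overlap of articles
across questions (universes are disjoint by construction). Passing
simulation-based tests therefore certifies the pipeline's arithmetic
and the generator's calibration, not the behaviour of live PubMed
searches.

## Problem sizes and tolerances

Simulation-backed tests use 300–2000 questions depending on the
statistical check, sized so Monte-Carlo assertions (3 standard errors)
are stable across seeds while the whole suite runs in seconds.
Calibration checks accept the simulated median within ±1 of the target
for gold sizes and within roughly ±25–35% for output-size medians
(sum of a skewed size draw and the retained-relevant count). The
directional narrow-vs-unfiltered comparison uses 500 questions and
asserts ordering only, not magnitudes.

## Known limitations

- The evaluator assumes outputs are pre-capped to the review's date
  window; it carries no per-article dates.
- Binary relevance only: every gold trial counts equally, and
  non-gold items are uniformly irrelevant.
- The live E-utilities adapter is intentionally out of the tested
  surface; the package's contract ends at ranked-identifier files.
- Filter texts are best-effort defaults; evaluations of *rendered
  queries* against today's PubMed will not reproduce a 2010-era
  database state (hit counts are irreproducible in principle).
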