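"""Score a single ranked search output against a gold standard.

The gold standard is the set of PubMed-indexed trials a systematic
review included for the question; sensitivity is the share of those the
search retrieved, PPV the share of screened items that were relevant,
and NNR (= 1/PPV) the expected number of items read per relevant find.
"""

from picosearch import GoldStandard, RankedOutput, cumulative_curve, evaluate

gold = GoldStandard(
    question_id="caffeine-asthma",
    included_ids=frozenset(f"pmid{i}" for i in range(7)),
    indexed_ids=frozenset(f"pmid{i}" for i in range(7)),
)
# a 9-item output whose first six items are gold articles
output = RankedOutput(
    "caffeine-asthma", "S1",
    tuple(f"pmid{i}" for i in range(6)) + ("other1", "other2", "other3"),
)

full = evaluate(output, gold, "full")
print(f"full output : sensitivity {full.sensitivity_pct}%  "
      f"PPV {full.ppv_pct}%  NNR {full.nnr}")

two_page = evaluate(output, gold, 40)
print(f"2-page (40) : sensitivity {two_page.sensitivity_pct}%  "
      f"PPV {two_page.ppv_pct}%  (only {two_page.n_screened} items exist)")

print("cumulative sensitivity by rank:",
      cumulative_curve(output, gold, 9))

# 6 of 7 gold articles appear in the 9 retrieved items: sensitivity
# 85.7%, PPV 66.7% (6/9). The PPV denominator is what was actually
# screened, min(cutoff, output size), so the 40-item cutoff changes nothing.
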