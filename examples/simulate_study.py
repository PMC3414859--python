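"""Simulate a full evaluation study offline and run the whole pipeline.

The default calibration mimics a 30-question study: log-normal gold
sizes (median ~12 indexed trials), 85% PubMed indexing, and four output
models (unfiltered / broad filter / narrow filter / related articles)
with the output sizes, filter retention and rank concentration such
searches exhibit.
"""

from picosearch import StudyDataset, default_config, run_pipeline, simulate_study

study = simulate_study(default_config(), seed=1)
dataset = StudyDataset.from_simulation(study)

bundle = run_pipeline(
    dataset,
    cutoffs=(40, "full"),
    comparisons=[("unfiltered", "narrow")],
    curve_max_rank=60,
)

print("strategy summaries (median over 30 simulated questions):")
for entry in bundle["summaries"]:
    s = entry["summary"]
    print(f"  {s.strategy_id:>10} @ {str(entry['cutoff']):>4}: "
          f"hits {s.hits_median:6.1f}  sensitivity {s.sens_median:5.1f}%  "
          f"PPV {s.ppv_median:5.1f}%")

rep = bundle["comparisons"][0]
print(f"\nnarrow vs unfiltered @40: {rep.n_increased} improved / "
      f"{rep.n_stable} stable / {rep.n_decreased} decreased, "
      f"p = {rep.p_two_sided:.1e}")
print("median cumulative sensitivity of 'narrow' at ranks 10/20/40/60:",
      [bundle["curves"]["narrow"][k - 1] for k in (10, 20, 40, 60)])

# The simulation reproduces the qualitative signature of real searches:
# the narrow filter loses a little full-output sensitivity (its filter
# retention is 0.93) but concentrates relevant trials early, so within a
# 40-item screening budget it dominates the unfiltered search.
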