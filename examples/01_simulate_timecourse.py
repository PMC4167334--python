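"""Simulate a pooled-library vernalization time course with planted archetypes.

One negative-binomial count library per sampling day (day 0 before the
cold, days 2/28/63 during it, day 70 after a week of long days), each
gene following one of ten idealized log2 trajectories.
"""

import vernalseq as vs

cfg = vs.SimulationConfig(n_genes=1000, seed=1)
counts, samples, truth = vs.generate_timecourse(cfg)

print("sample sheet:")
print(samples[["tissue", "time_days", "phase", "size_factor"]].round(3))
print("\nfirst genes x samples counts:")
print(counts.head(4))
print("\nplanted archetype counts (who responds and how):")
print(truth["label"].value_counts().to_string())
print(
    "\nEach non-null gene moves by delta_log2 =", cfg.delta_log2,
    "log2 units along its archetype shape; 'null_flat' genes are the",
    "non-responsive background the DE stage must not flag.",
)
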