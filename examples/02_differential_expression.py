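"""No-replicate differential expression across all pairs of time points.

With one library per time point there are no replicates, so dispersion
is estimated blind (all libraries treated as one condition) and each
pair of days is compared with an exact conditional NB test.
"""

import vernalseq as vs

cfg = vs.SimulationConfig(n_genes=1000, seed=1)
counts, samples, truth = vs.generate_timecourse(cfg)
cm = vs.CountMatrix(counts=counts, samples=samples)
grid = cfg.grid

results, union, info = vs.pairwise_de(cm, grid, alpha=0.05)
fit = info["fit"]

print("size factors (median-of-ratios):")
print(info["size_factors"].round(3).to_string())
print(f"\nblind dispersion fit: alpha(mu) = {fit.a0:.4f} + {fit.a1:.2f}/mu")
print("\nsignificant transcripts per comparison (padj < 0.05):")
for r in results:
    n_sig = int(r.table["significant"].sum())
    print(f"  day {r.time_a:>4g} vs day {r.time_b:>4g}: {n_sig:4d}")
print(f"\nunion over all {len(results)} comparisons: {len(union)} DE transcripts")

non_null = set(truth.index[~truth["is_null"]])
recall = len(union & non_null) / len(non_null)
fdr = len(union - non_null) / len(union)
print(
    f"against the planted truth: recall {recall:.3f}, false discovery "
    f"rate {fdr:.3f} — the blind-dispersion test finds most responsive "
    "genes while keeping false positives near the nominal level."
)
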