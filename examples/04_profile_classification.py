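"""Label cluster centroids with interpretive expression-profile classes.

The rule set formalizes how time-course clusters are read: an early-cold
spike is a stress response, sustained cold up-regulation that collapses
at long days is cold acclimation, gradual or late rises through the cold
mark putative vernalization-mediated flowering promoters (mirrored
classes mark repressors), long-day-only changes mark secondary
induction.
"""

import numpy as np

import vernalseq as vs

grid = vs.leaf_grid()

print("hand-built centroids and their labels (tau = 1 SD):")
demos = {
    "early spike": [0, 3, 0, 0, 0],
    "sustained cold, off at long days": [0, 3, 3, 3, 0],
    "gradual rise through cold": [0, 0.3, 1.5, 3, 3],
    "long-day only": [0, 0, 0, 0, 3],
    "flat": [2, 2, 2, 2, 2],
}
for name, c in demos.items():
    label = vs.classify_centroid(np.array(c, float), grid)
    print(f"  {name:38s} -> {label}")

cfg = vs.SimulationConfig(n_genes=1000, seed=1)
counts, samples, truth = vs.generate_timecourse(cfg)
cm = vs.CountMatrix(counts=counts, samples=samples)
results, union, info = vs.pairwise_de(cm, grid, alpha=0.05)
vst_df = vs.vst(counts, info["size_factors"], info["fit"])
genes = sorted(union)
Z = vs.standardize_profiles(
    vst_df.loc[genes].to_numpy(),
    noise_sd=np.sqrt(info["fit"].a0) / np.log(2.0),
)
model = vs.fit_kmeans(Z, grid, K=9, seed=1, n_restarts=10)

table = vs.classify_model(model, grid)
print("\nfitted clusters on the simulated leaf course:")
print(table.to_string(index=False))
print(
    "\nWith nine clusters and nine planted archetypes the labels should"
    " recover the planted classes; 'unclassified' flags centroids that"
    " match no rule at the configured threshold."
)
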