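# Methods

## Study design being modeled

The package targets a two-step floral-induction time course in a
vernalization-requiring grass: plants held under short days, then given
nine weeks of cold (primary induction), then shifted to warm long days
(secondary induction). Leaves are sampled before the cold, at 2 days,
4 weeks and 9 weeks of cold, and after 7 long days (calendar days
{0, 2, 28, 63, 70}); meristem-enriched tissue at 9 weeks of cold and
after 1 and 7 long days ({63, 64, 70}). One pooled RNA-seq library is
sequenced per tissue and time point — there are no biological
replicates, which drives every statistical choice below.

## Synthetic data generator

`generate_timecourse` draws, per gene, an archetype label from the
configured mix, a baseline log2 expression, and NB counts around the
planted trajectory:

* mean of gene *g* in library *j*: `s_j * 2^{m_g(t_j)}`, with
  `m_g = baseline + delta_log2 * shape_g` and `s_j ~ logNormal(0, size_factor_sd^2)`;
* variance `mu + alpha(mu) * mu^2` with `alpha(mu) = a0 + a1/mu`,
  evaluated at the normalized mean — the same family the DE module
  fits, so simulate→estimate loops close exactly;
* `alpha = 0` falls back to Poisson sampling.

Archetype shapes are minimal piecewise encodings of the interpretive
classes (anchored at 0 at the first grid point): an early-cold spike
(transient stress), a sustained cold plateau that returns at long days
(cold acclimation), gradual `(0, 0.15, 0.6, 1, 1)` and late
`(0, 0, 0.1, 1, 1)` vernalization responses with mirrored down-classes,
long-day-only steps, and a flat null. The 3-point meristem grid admits
only the spike, long-day and null shapes (no mid/late-cold points
exist).

Defaults, chosen once as the study conditions: 2,000 genes; mix = 55%
null + 5% for each of the nine responsive classes (a mostly-null
transcriptome with enough signal per class to measure recovery);
`delta_log2 = 2` (a 4-fold swing, typical of the strongly regulated
transcripts time-course studies highlight); baseline `~ U[6, 10]` log2
(counts ~64–1000, the informative mid-range of a library);
`(a0, a1) = (0.02, 2)` (asymptotic CV ~14%, shot-noise dominated below
~100 counts — ordinary bulk-RNA-seq behavior); `size_factor_sd = 0.2`
(±20% library-depth scatter). One library per time point mirrors the
pooled design; `n_replicates` exists for calibration experiments.

What the generator does **not** emulate: transcript-length effects,
isoform ambiguity and mapping noise, correlated genes (each gene is
independent), GC/batch trends, or genotype-specific sequence variation.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to every artifact of
real libraries.

## Size factors and blind dispersion

Size factors are DESeq-style median-of-ratios over genes positive in
every sample; estimation fails loudly if no such gene exists.

With no replicates, all samples of a tissue are pooled ("blind") for
dispersion estimation. For normalized counts the per-gene moment
estimator is

    alpha_hat = (v_hat - mu_hat * xi) / mu_hat^2,   xi = mean(1/s_j),

whose raw (possibly negative) values are kept for curve fitting —
truncating at zero first would bias the fit upward at n = 5 samples.

Fitting `alpha(mu) = a0 + a1/mu` must resist the genes that are *really*
regulated: their blind variance contains the biological trajectory and
can exceed the technical trend ten-fold, and a plain mean-type fit
absorbs it (we measured a0 inflating ~8x on the default scenario, which
zeroes test power). The fit therefore proceeds in three steps:

1. **Robust trend**: median (L1) regression of chi-square-median-
   corrected dispersions on 1/mu. The correction divides each variance
   estimate by `median(chi2_k)/k` (k = n−1 degrees of freedom), making
   the regression target median-unbiased for the true curve.
2. **Outlier trimming, iterated**: genes whose observed variance
   exceeds the 99.9th percentile of its `v_fit * chi2_k/k` sampling
   distribution under the current robust fit are excluded and the L1
   fit repeated until the kept set stabilizes (≤10 rounds). Median
   regression is used *inside* the loop deliberately: a mean-type
   refit creates positive feedback (capped outliers raise the fit,
   which loosens the trim), which we observed diverging.
3. **Final estimate**: one gamma-weighted IRLS pass (weights
   1/fitted², the identity-link gamma-family scheme) on the kept genes
   restores mean-unbiasedness. On pure-null data the trim removes only
   the 0.1% sampling tail, and planted (a0, a1) = (0.02, 2) at 5,000
   genes x 5 samples is recovered within a few percent.

Fallbacks (logged): the robust L1 parameters if IRLS degenerates, then
the median per-gene dispersion with a1 = 0.

## Exact conditional test

For libraries A and B, conditioning on the total count removes the
nuisance mean: with pooled normalized mean `q = (kA/sA + kB/sB)/2`,
each split (a, total−a) has probability proportional to
`NB(a; q*sA) * NB(total−a; q*sB)`, with variances `mu + alpha(q)*mu^2`
(the dispersion is evaluated at the pooled mean, the scale on which it
was fitted). The two-sided p-value sums splits no more likely than the
observed one; ties are included with a 1e-8 log-tolerance so the
symmetric case `kA = kB, sA = sB` yields exactly p = 1. An all-zero
pair returns p = 1 by convention. Computation enumerates the total in
one vectorized pass (O(total) per gene), exact for any count the
pooled design produces.

Per comparison, p-values are Benjamini–Hochberg adjusted
(statsmodels); significance defaults to padj < 0.05 — the threshold is
configurable because no universal cutoff exists for this design — and
the DE union across all C(n,2) comparisons feeds clustering. Genes
with zero counts everywhere are dropped and counted in the run
metadata. Blind dispersion makes the test conservative by construction
(signal inflates the variance estimate); null simulations show
per-comparison rejection well under the nominal level.

## Variance-stabilizing transformation

With `v(mu) = (1+a1)*mu + a0*mu^2` (the fitted variance of normalized
counts, shot noise folded into 1+a1), the stabilizer
`integral dmu/sqrt(v)` has the closed form
`raw(mu) = (2/sqrt(a0)) * asinh(sqrt(a0*mu/(1+a1)))`. It is calibrated
as `A*raw + B` with `A = sqrt(a0)/ln 2` and
`B = -2*log2(2*sqrt(a0/(1+a1)))`, the unique affine map under which
`vst(mu) -> log2(mu)` as mu grows, so values read as log2 expression.
At a0 = 0 no log-like calibration exists and the Poisson-limit
`2*sqrt(mu/(1+a1))` is returned with a warning. The closed form matches
numeric quadrature to ~1e-14 relative, and the SD of transformed NB
replicates varies by <4% across means 2^4–2^14 under the default
dispersion.

## Time-weighted K-means

Uneven sampling makes plain profile distances misleading: days 0 and 2
would count as much as month-apart samples. Each grid point receives
the trapezoid (Voronoi) width of its node, normalized by the span —
for {0, 2, 28, 63, 70}: {1, 14, 30.5, 21, 3.5}/70 — and distances are
`sqrt(sum_i w_i (x_i - y_i)^2)`. Weights summing to 1 make a constant
offset c between profiles have distance exactly |c|, keeping the scale
interpretable in VST units.

Because the weights factor out of the centroid minimization, the
update remains the plain per-time-point mean, and the whole algorithm
is *exactly* standard K-means on coordinates scaled by sqrt(w_i). This
reduction is the module's correctness anchor: tests require identical
assignments and inertia (1e-10 relative) against scikit-learn's Lloyd
on scaled coordinates, exhaustive optimality on ≤8-profile instances,
and monotone non-increasing inertia (asserted every iteration).

Numerical choices: k-means++ seeding under the weighted metric with
tie-breaks to the lowest index; `n_restarts = 10` independent child
streams of the seed, best inertia wins (tiny instances deserve more —
the exhaustive-optimality check uses 50, since with ≤8 profiles the
D²-sampling needs many draws to cover every basin); `max_iter = 300`;
convergence on an exact assignment fixed point or relative inertia
improvement < 1e-6; empty clusters re-seeded with the farthest
profile; K defaults to 50 (leaf) / 25 (meristem), overridable.
Cluster ids are 1-based in all outputs.

Clustering operates on raw VST profiles by default (their absolute
level is meaningful). For *shape-class recovery* — the archetype
experiments — the standardization option is the right configuration:
`standardize_profiles(X, noise_sd)` z-scores each profile with a
variance floor, dividing by `sqrt(var + noise_sd^2)` rather than the
bare SD. The natural floor is the stabilized VST noise,
`sqrt(a0)/ln 2`: profiles whose amplitude is at the noise floor are
*not* inflated to unit amplitude (a plain z-score turns pure noise
into random unit-vectors that contaminate shape clusters). The
pipeline exposes this as `standardize: true`.

## Profile classification

Centroids are z-scored (population SD; constant centroids are
`null_flat`), and baseline-relative deviations `d_role = z_role −
z_baseline` are thresholded at `tau` SD units (default 1, with tau/2 as
the "quiet" band). Rules fire in a fixed order, first match wins:
transient stress up (early spike, quiet mid/late), cold acclimation
(early+mid+late up, long-day back down), gradual vernalization up
(mid ≥ tau/2, late ≥ tau, quiet early, maintained at long days), late
vernalization up (late ≥ tau, quiet early/mid), long-day up (only the
long-day point moves), then the mirrored down-classes in the same
relative order. Negating a centroid maps every mirrored class to its
partner (property-tested); cold acclimation has no mirror in the
vocabulary, so its negation is unclassified. Grids without mid/late
cold points (meristem) admit only the transient and long-day classes,
with the 9-weeks-of-cold sample as baseline. The thresholds and
precedence are this package's codification of what is usually read by
eye; both are configurable, and `unclassified` is an explicit outcome
rather than a forced assignment.

## Ordination, enrichment, summaries

Classical (Torgerson) MDS double-centers the squared Euclidean
distance matrix of the VST sample columns and scales the top
eigenvectors by sqrt(eigenvalue); eigenvalues are reported so the
caller can judge dimensionality. Distances use all genes, not just DE
genes. Fisher's exact test (two-sided by default, since both over- and
under-representation are of interest) scores term enrichment of a DE
set against its universe at a raw p < 0.01 cutoff; BH adjustment is
available but off by default, mirroring common practice for these
screens. Overlap and per-comparison count tables satisfy
inclusion–exclusion by construction.

## Orchestration and determinism

`run_all` executes de → mds → cluster → classify → enrich → report
from one config; disabling a prerequisite skips its dependents with a
logged notice. All randomness flows from the single seed (restart
streams are spawned from it); rerunning a config reproduces every data
artifact byte for byte. The `run_metadata.json` sidecar records the
config echo, package version, per-stage wall-clock timings and
dropped-record counts — as a timing record it is the one output
excluded from the byte-identity guarantee. Artifacts are plain TSV
with one JSON sidecar per run.

Default problem sizes for the validation experiments (2,000 genes for
end-to-end scenarios, 5,000 × 5 for parameter recovery, 500 profiles ×
20 seeds for the scaling reduction) are desk-scale: each experiment
runs in seconds to a few tens of seconds on one CPU while leaving the
Monte-Carlo error well below the effect sizes being checked.

## Known limitations

* The exact test inherits the conservativeness of blind dispersion;
  with many strongly regulated genes, power depends on the robust trend
  fit finding the unregulated majority (breakdown near 50% regulated).
* The dispersion trim threshold assumes approximately chi-square
  variance sampling; very heavy-tailed counts (a0 >> 0.1) weaken the
  median correction.
* Archetype recovery is measured against genes carrying a planted
  class; null false positives admitted at the configured FDR scatter
  across clusters and are not part of that metric.
* K is fixed by the caller (50/25 defaults); no model selection is
  attempted.
* GO-style enrichment treats terms as flat labels — no ontology graph
  propagation.
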