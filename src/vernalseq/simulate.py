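"""Synthetic negative-binomial time-course counts with planted profile archetypes.

Emulates a pooled-library vernalization time course: one RNA-seq library
per (tissue, time point), integer counts per transcript, overdispersed
around a planted mean trajectory.  Each gene is assigned an archetype —
an idealized expression trajectory class on the log2 scale — so that
downstream differential-expression, clustering and classification stages
can be scored against known truth.

Counts follow NB(mean = s_j * 2^{m_g(t_j)}) with variance mu + alpha(mu)
* mu^2 and alpha(mu) = a0 + a1 / mu, the same mean-dispersion family the
DE module fits, closing the simulate -> estimate loop.  Per-sample
library scalings s_j are log-normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import TimeGrid, leaf_grid
from .profiles import LABELS

logger = logging.getLogger(__name__)

#: default archetype shapes on the 5-point leaf grid (log2-scale
#: multipliers, anchored at 0 at the pre-induction point)
LEAF_SHAPES: dict[str, tuple[float, ...]] = {
    "transient_stress_up": (0, 1, 0, 0, 0),
    "transient_stress_down": (0, -1, 0, 0, 0),
    "cold_acclimation": (0, 1, 1, 1, 0),
    "gradual_vern_up": (0, 0.15, 0.6, 1, 1),
    "late_vern_up": (0, 0, 0.1, 1, 1),
    "gradual_vern_down": (0, -0.15, -0.6, -1, -1),
    "late_vern_down": (0, 0, -0.1, -1, -1),
    "long_day_up": (0, 0, 0, 0, 1),
    "long_day_down": (0, 0, 0, 0, -1),
    "null_flat": (0, 0, 0, 0, 0),
}

#: 3-point meristem grid (anchor = the 9-weeks-of-cold point)
MERISTEM_SHAPES: dict[str, tuple[float, ...]] = {
    "transient_stress_up": (0, 1, 0),
    "transient_stress_down": (0, -1, 0),
    "long_day_up": (0, 0, 1),
    "long_day_down": (0, 0, -1),
    "null_flat": (0, 0, 0),
}

#: default archetype mix for the leaf scenario: a mostly-null
#: transcriptome with the nine responsive classes planted evenly
DEFAULT_LEAF_MIX: dict[str, float] = {
    "null_flat": 0.55,
    **{k: 0.05 for k in LEAF_SHAPES if k != "null_flat"},
}


def default_shapes(grid: TimeGrid) -> dict[str, tuple[float, ...]]:
    """Archetype shape dictionary matching a grid's length/tissue."""
    if grid.tissue == "leaf" and len(grid) == 5:
        return LEAF_SHAPES
    if grid.tissue == "meristem" and len(grid) == 3:
        return MERISTEM_SHAPES
    raise ValueError(
        f"no default shapes for a {len(grid)}-point {grid.tissue} grid; "
        "supply ArchetypeSpec shapes explicitly"
    )


@dataclass(frozen=True)
class ArchetypeSpec:
    """One planted trajectory class.

    ``baseline_log2`` is the log2 mean expression at the anchor point,
    ``delta_log2`` the effect size in log2 units, and ``shape`` the
    per-time-point multiplier pattern (one value per grid point).
    """

    label: str
    baseline_log2: float
    delta_log2: float
    shape: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.delta_log2 < 0:
            raise ValueError("delta_log2 must be >= 0")
        if self.label == "null_flat" and self.delta_log2 != 0:
            raise ValueError("null_flat implies delta_log2 == 0")


def archetype_profile(spec: ArchetypeSpec, grid: TimeGrid) -> np.ndarray:
    """Planted log2 mean trajectory: baseline + delta * shape."""
    shape = np.asarray(spec.shape, dtype=float)
    if len(shape) != len(grid):
        raise ValueError(
            f"shape has {len(shape)} values but grid has {len(grid)} points"
        )
    return spec.baseline_log2 + spec.delta_log2 * shape


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for one simulated tissue time course.

    ``archetype_mix`` gives the expected gene fraction per archetype
    label (must sum to 1).  ``dispersion_params`` are (a0, a1) of
    alpha(mu) = a0 + a1/mu; ``size_factor_sd`` the log-normal SD of the
    per-library scaling; ``baseline_log2_range`` the per-gene uniform
    range of baseline expression; ``n_replicates`` the number of
    libraries per time point (1 mirrors the pooled design).
    """

    grid: TimeGrid = field(default_factory=leaf_grid)
    n_genes: int = 2000
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEAF_MIX)
    )
    delta_log2: float = 2.0
    baseline_log2_range: tuple[float, float] = (6.0, 10.0)
    dispersion_params: tuple[float, float] = (0.02, 2.0)
    size_factor_sd: float = 0.2
    n_replicates: int = 1
    genotype: str = "genotypeA"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        total = sum(self.archetype_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"archetype_mix must sum to 1, got {total}")
        unknown = set(self.archetype_mix) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown archetype labels: {sorted(unknown)}")
        a0, a1 = self.dispersion_params
        if a0 < 0 or a1 < 0:
            raise ValueError("dispersion_params must be non-negative")
        if self.size_factor_sd < 0:
            raise ValueError("size_factor_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw NB counts with variance mean + alpha * mean^2 (Poisson at alpha=0)."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        n = 1.0 / alpha[~pois]
        p = n / (n + mean[~pois])
        out[~pois] = rng.negative_binomial(n, p)
    return out


def generate_timecourse(config: SimulationConfig):
    """Simulate a count matrix and its truth table.

    Returns ``(counts, samples, truth)``: a genes x samples integer
    DataFrame, the sample sheet (sample, genotype, tissue, time_days,
    phase, size_factor), and the per-gene truth table (planted label,
    is_null flag, planted per-time-point normalized means).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    n_t = len(grid)
    shape_table = default_shapes(grid)
    for lab in config.archetype_mix:
        if lab not in shape_table:
            raise ValueError(
                f"label {lab!r} has no shape on a {len(grid)}-point {grid.tissue} grid"
            )

    labels = list(config.archetype_mix)
    probs = np.array([config.archetype_mix[k] for k in labels])
    gene_labels = rng.choice(len(labels), size=config.n_genes, p=probs / probs.sum())
    baselines = rng.uniform(*config.baseline_log2_range, size=config.n_genes)

    # planted log2 means, gene x time
    m = np.empty((config.n_genes, n_t))
    for i, lab_idx in enumerate(gene_labels):
        lab = labels[lab_idx]
        delta = 0.0 if lab == "null_flat" else config.delta_log2
        spec = ArchetypeSpec(lab, baselines[i], delta, shape_table[lab])
        m[i] = archetype_profile(spec, grid)
    mu = 2.0**m  # normalized-scale means

    n_samples = n_t * config.n_replicates
    sf = (
        np.exp(rng.normal(0.0, config.size_factor_sd, n_samples))
        if config.size_factor_sd > 0
        else np.ones(n_samples)
    )

    a0, a1 = config.dispersion_params
    with np.errstate(divide="ignore"):
        alpha = a0 + np.where(mu > 0, a1 / mu, np.inf)

    sample_names, times, phases = [], [], []
    cols = []
    j = 0
    for t_idx in range(n_t):
        for r in range(config.n_replicates):
            name = f"{grid.tissue}_d{grid.times[t_idx]:g}"
            if config.n_replicates > 1:
                name += f"_r{r + 1}"
            sample_names.append(name)
            times.append(grid.times[t_idx])
            phases.append(grid.phases[t_idx])
            scaled = sf[j] * mu[:, t_idx]
            cols.append(_nb_sample(rng, scaled, alpha[:, t_idx]))
            j += 1

    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    counts = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(gene_ids, name="gene"),
        columns=sample_names,
    )
    samples = pd.DataFrame(
        {
            "sample": sample_names,
            "genotype": config.genotype,
            "tissue": grid.tissue,
            "time_days": times,
            "phase": phases,
            "size_factor": sf,
        }
    ).set_index("sample")

    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "label": [labels[i] for i in gene_labels],
            "is_null": [labels[i] == "null_flat" for i in gene_labels],
        }
    ).set_index("gene")
    for t_idx, t in enumerate(grid.times):
        truth[f"mu_d{t:g}"] = mu[:, t_idx]
    return counts, samples, truth


def synthetic_annotation(
    truth: pd.DataFrame,
    seed: int = 0,
    terms_per_label: int = 2,
    n_background_terms: int = 20,
    p_label_term: float = 0.8,
    p_background_term: float = 0.1,
) -> dict[str, set[str]]:
    """Build a synthetic GO-style annotation table keyed to planted labels.

    Each non-null archetype gets ``terms_per_label`` dedicated terms that
    its genes carry with probability ``p_label_term``; every gene also
    carries each of ``n_background_terms`` unrelated terms with
    probability ``p_background_term``.  Gene sets drawn from one
    archetype are therefore genuinely enriched for its terms, giving the
    enrichment stage something real to find.
    """
    rng = np.random.default_rng(seed)
    annot: dict[str, set[str]] = {g: set() for g in truth.index}
    bg_terms = [f"GO:BG{j:04d}" for j in range(n_background_terms)]
    for gene, row in truth.iterrows():
        terms = annot[gene]
        if not row["is_null"]:
            for j in range(terms_per_label):
                if rng.random() < p_label_term:
                    terms.add(f"GO:{row['label'].upper()}_{j}")
        for t in bg_terms:
            if rng.random() < p_background_term:
                terms.add(t)
    return annot
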