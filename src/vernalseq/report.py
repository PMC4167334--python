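"""Sample ordination, term enrichment and DE-set summary tables.

Covers the descriptive outputs of a time-course DE analysis: a classical
(Torgerson) MDS embedding of the samples from their variance-stabilized
expression, Fisher's exact enrichment of annotation terms in a gene set
against a universe, and the common/specific overlap and per-comparison
count tables used to summarize DE results across tissues.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import linalg, stats

logger = logging.getLogger(__name__)


def mds_embedding(vst_df: pd.DataFrame, dims: int = 2):
    """Classical MDS of the sample columns of an expression matrix.

    Euclidean distances between sample columns are double-centered
    (Torgerson) and the top ``dims`` eigenvectors, scaled by the square
    root of their eigenvalues, give the coordinates.  Returns
    ``(coords, eigenvalues)`` with coords indexed by sample; all
    eigenvalues of the centered matrix are reported in decreasing order.
    """
    X = vst_df.to_numpy(dtype=float).T  # samples x genes
    n = X.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} samples for {dims}-D MDS")
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ sq @ J
    evals, evecs = linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:dims], 0.0, None)
    coords = evecs[:, :dims] * np.sqrt(lam)[None, :]
    out = pd.DataFrame(
        coords,
        index=vst_df.columns,
        columns=[f"dim{i + 1}" for i in range(dims)],
    )
    return out, evals


def fisher_enrichment(
    study: set,
    universe: set,
    annot: dict[str, set],
    cutoff: float = 0.01,
    alternative: str = "two-sided",
    bh: bool = False,
) -> pd.DataFrame:
    """Fisher's exact test for term over-/under-representation.

    For every annotation term present in the universe, the 2x2 table
    (in study x carries term) is tested; a term is flagged enriched when
    its (optionally BH-adjusted) p-value falls below ``cutoff``.  The
    reported direction is "over" when the study-term frequency exceeds
    the universe frequency, "under" otherwise.  Terms carried by no
    universe gene are skipped with a log message.  Raises if the study
    set is not contained in the universe.
    """
    study, universe = set(study), set(universe)
    if not study <= universe:
        extra = sorted(study - universe)[:5]
        raise ValueError(f"study set is not a subset of the universe: {extra}")
    n_universe = len(universe)
    n_study = len(study)

    term_genes: dict[str, set] = {}
    for gene in universe:
        for term in annot.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    skipped = [t for g, ts in annot.items() if g not in universe for t in ts
               if t not in term_genes]
    if skipped:
        logger.info("skipping %d terms absent from the universe", len(set(skipped)))

    rows = []
    for term in sorted(term_genes):
        carriers = term_genes[term]
        a = len(carriers & study)          # in study, has term
        b = n_study - a                    # in study, lacks term
        c = len(carriers) - a              # outside study, has term
        d = (n_universe - n_study) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        study_freq = a / n_study if n_study else 0.0
        uni_freq = len(carriers) / n_universe
        rows.append(
            {
                "term": term,
                "study_count": a,
                "study_size": n_study,
                "universe_count": len(carriers),
                "universe_size": n_universe,
                "p_value": float(p),
                "direction": "over" if study_freq > uni_freq else "under",
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term", "study_count", "study_size", "universe_count",
            "universe_size", "p_value", "direction",
        ],
    )
    if len(result):
        pcol = bh_column = result["p_value"].to_numpy()
        if bh:
            from .de import bh_adjust

            bh_column = bh_adjust(pcol)
            result["padj"] = bh_column
        result["enriched"] = bh_column < cutoff
    else:
        result["enriched"] = pd.Series(dtype=bool)
    return result


def overlap_summary(de_sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise common/specific counts between named DE gene sets.

    One row per unordered pair of set names with the sizes, the
    intersection, and each side's exclusive count; satisfies
    |A| = |A ∩ B| + |A \\ B| by construction.
    """
    if len(de_sets) < 2:
        raise ValueError("need at least 2 named gene sets")
    rows = []
    for name_a, name_b in itertools.combinations(sorted(de_sets), 2):
        a, b = set(de_sets[name_a]), set(de_sets[name_b])
        rows.append(
            {
                "set_a": name_a,
                "set_b": name_b,
                "size_a": len(a),
                "size_b": len(b),
                "common": len(a & b),
                "specific_a": len(a - b),
                "specific_b": len(b - a),
            }
        )
    return pd.DataFrame(rows)


def comparison_matrix(de_results) -> pd.DataFrame:
    """Symmetric table of significant-gene counts per time-point pair."""
    times = sorted({t for r in de_results for t in (r.time_a, r.time_b)})
    labels = [f"d{t:g}" for t in times]
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for r in de_results:
        n_sig = int(r.table["significant"].sum())
        ia, ib = f"d{r.time_a:g}", f"d{r.time_b:g}"
        table.loc[ia, ib] = n_sig
        table.loc[ib, ia] = n_sig
    return table


def plot_centroid_grid(model, grid, path=None, ncols: int = 5):
    """Small-multiple plot of cluster centroids over calendar time."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    K = model.K
    nrows = int(np.ceil(K / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(2.2 * ncols, 1.8 * nrows), squeeze=False
    )
    t = grid.times_array
    for k in range(K):
        ax = axes[k // ncols][k % ncols]
        ax.plot(t, model.centroids[k], marker="o", ms=3)
        ax.set_title(f"cluster {k + 1}", fontsize=8)
    for k in range(K, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
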