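"""Single-config end-to-end runner: DE -> VST -> MDS -> clustering -> labels -> enrichment.

Orchestrates the stage chain on a counts TSV + sample sheet, writing
every artifact and a JSON run-metadata file under one output directory.
All randomness flows from the single configured seed; the data outputs
are byte-identical across reruns with the same config (the metadata
sidecar records wall-clock timings and is the one file excluded from
that guarantee).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import fit_kmeans, cluster_report, standardize_profiles, time_weights
from .de import pairwise_de, vst
from .grids import TimeGrid
from .io import (
    read_annotation,
    read_counts,
    write_de_result,
    write_gene_set,
    write_metadata,
    write_table,
)
from .profiles import ClassifierConfig, classify_model
from .report import comparison_matrix, fisher_enrichment, mds_embedding

logger = logging.getLogger(__name__)

STAGES = ("de", "mds", "cluster", "classify", "enrich", "report")
#: stage -> stages it needs
DEPENDS = {
    "mds": ("de",),
    "cluster": ("de",),
    "classify": ("cluster",),
    "enrich": ("de",),
    "report": ("de",),
}

DEFAULT_K = {"leaf": 50, "meristem": 25}


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    ``k`` of ``None`` picks the tissue default (50 for leaf, 25 for
    meristem).  ``stages`` lists the stages to run; dependencies are
    enforced (a stage whose prerequisite is disabled is skipped with a
    notice).
    """

    counts: str | Path
    samples: str | Path
    outdir: str | Path
    annotation: str | Path | None = None
    alpha: float = 0.05
    k: int | None = None
    tau: float = 1.0
    seed: int = 1
    n_restarts: int = 10
    standardize: bool = False
    enrich_cutoff: float = 0.01
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunMetadata:
    config: dict
    version: str
    timings: dict[str, float] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    stats: dict = field(default_factory=dict)


def grid_from_samples(samples: pd.DataFrame) -> TimeGrid:
    """Reconstruct the time grid from a sample sheet (one tissue)."""
    tissues = samples["tissue"].unique()
    if len(tissues) != 1:
        raise ValueError(f"sample sheet mixes tissues {list(tissues)}")
    sub = samples[["time_days", "phase"]].drop_duplicates().sort_values("time_days")
    return TimeGrid(
        times=tuple(float(t) for t in sub["time_days"]),
        phases=tuple(sub["phase"]),
        tissue=str(tissues[0]),
    )


def run_all(config: RunConfig) -> RunMetadata:
    """Execute the enabled stages in dependency order.

    Any stage failure aborts with the stage name in the exception;
    outputs of completed stages are preserved in ``outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = RunMetadata(config={**asdict(config), "stages": list(config.stages)},
                       version=__version__)

    enabled = []
    for stage in STAGES:
        if stage not in config.stages:
            continue
        needs = DEPENDS.get(stage, ())
        missing = [d for d in needs if d not in config.stages]
        if missing:
            note = f"stage {stage!r} skipped: requires disabled {missing}"
            logger.warning(note)
            meta.notes.append(note)
            continue
        enabled.append(stage)

    cm = read_counts(config.counts, config.samples)
    grid = grid_from_samples(cm.samples)
    state: dict = {}

    for stage in enabled:
        t0 = time.perf_counter()
        try:
            _STAGE_FNS[stage](config, cm, grid, state, outdir, meta)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        meta.timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, meta.timings[stage])

    write_metadata(asdict(meta), outdir / "run_metadata.json")
    return meta


def _stage_de(config, cm, grid, state, outdir, meta):
    results, union, info = pairwise_de(cm, grid, alpha=config.alpha)
    state.update(de_results=results, union=union, de_info=info)
    for r in results:
        write_de_result(r, outdir / f"de_d{r.time_a:g}_vs_d{r.time_b:g}.tsv")
    write_gene_set(union, outdir / "de_union.txt")
    fit = info["fit"]
    vst_df = vst(cm.counts.loc[cm.counts.sum(axis=1) > 0], info["size_factors"], fit)
    state["vst"] = vst_df
    write_table(vst_df, outdir / "vst.tsv", index_label="gene")
    meta.dropped["all_zero_genes"] = info["n_dropped"]
    meta.stats["dispersion_fit"] = {"a0": fit.a0, "a1": fit.a1}
    meta.stats["n_de_union"] = len(union)
    meta.stats["size_factors"] = info["size_factors"].round(6).to_dict()


def _stage_mds(config, cm, grid, state, outdir, meta):
    coords, evals = mds_embedding(state["vst"], dims=2)
    write_table(coords, outdir / "mds_coordinates.tsv", index_label="sample")
    meta.stats["mds_eigenvalues"] = [float(v) for v in evals]


def _stage_cluster(config, cm, grid, state, outdir, meta):
    union = sorted(state["union"])
    if not union:
        raise ValueError("no differentially expressed genes to cluster")
    k = config.k or DEFAULT_K.get(grid.tissue, 10)
    k = min(k, len(union))
    X = state["vst"].loc[union].to_numpy()
    if config.standardize:
        fit = state["de_info"]["fit"]
        noise_sd = np.sqrt(fit.a0) / np.log(2.0) if fit.a0 > 0 else 0.0
        X = standardize_profiles(X, noise_sd=noise_sd)
    model = fit_kmeans(
        X, grid, K=k, seed=config.seed, n_restarts=config.n_restarts
    )
    state["cluster_model"] = model
    state["cluster_genes"] = union
    membership, centroids = cluster_report(model, union)
    write_table(membership, outdir / "cluster_assignments.tsv", index_label="gene")
    write_table(centroids, outdir / "cluster_centroids.tsv", index_label="cluster")
    meta.stats["clustering"] = {
        "K": model.K,
        "inertia": model.inertia,
        "n_iter": model.n_iter,
        "converged": bool(model.converged),
        "weights": list(model.weights.weights),
        "seed": model.seed,
    }


def _stage_classify(config, cm, grid, state, outdir, meta):
    table = classify_model(
        state["cluster_model"], grid, ClassifierConfig(tau=config.tau)
    )
    write_table(table.set_index("cluster"), outdir / "cluster_labels.tsv",
                index_label="cluster")
    meta.stats["profile_labels"] = (
        table["label"].value_counts().sort_index().to_dict()
    )


def _stage_enrich(config, cm, grid, state, outdir, meta):
    if config.annotation is None:
        note = "stage 'enrich' skipped: no annotation table supplied"
        logger.warning(note)
        meta.notes.append(note)
        return
    annot = read_annotation(config.annotation)
    universe = set(state["vst"].index)
    study = set(state["union"]) & universe
    result = fisher_enrichment(
        study, universe, annot, cutoff=config.enrich_cutoff
    )
    write_table(result.set_index("term"), outdir / "enrichment.tsv",
                index_label="term")
    meta.stats["n_enriched_terms"] = int(result["enriched"].sum()) if len(result) else 0


def _stage_report(config, cm, grid, state, outdir, meta):
    table = comparison_matrix(state["de_results"])
    write_table(table, outdir / "comparison_matrix.tsv", index_label="time")


_STAGE_FNS = {
    "de": _stage_de,
    "mds": _stage_mds,
    "cluster": _stage_cluster,
    "classify": _stage_classify,
    "enrich": _stage_enrich,
    "report": _stage_report,
}
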