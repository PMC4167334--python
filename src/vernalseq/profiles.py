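"""Rule-based classification of cluster centroids into expression-profile classes.

A time-course clustering of vernalization-responsive transcripts yields
centroids whose shapes are read biologically: a spike at the first cold
sample is a stress response; sustained up-regulation through the cold
that collapses at long days is cold acclimation; a gradual or late rise
through the cold maintained into long days marks putative vernalization-
mediated flowering promoters (mirrored classes mark repressors); change
only at long days marks secondary-induction genes.  This module encodes
that reading as an explicit, configurable rule set over standardized
centroids, so the interpretation is testable instead of by-eye.

Centroids are z-scored first, making every rule scale- and shift-
invariant; thresholds are expressed in within-centroid SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import TimeGrid

#: closed label vocabulary
LABELS = (
    "transient_stress_up",
    "transient_stress_down",
    "cold_acclimation",
    "gradual_vern_up",
    "late_vern_up",
    "gradual_vern_down",
    "late_vern_down",
    "long_day_up",
    "long_day_down",
    "null_flat",
    "unclassified",
)

#: up-class -> down-class (and the reverse); cold_acclimation has no mirror
MIRROR = {
    "transient_stress_up": "transient_stress_down",
    "transient_stress_down": "transient_stress_up",
    "gradual_vern_up": "gradual_vern_down",
    "gradual_vern_down": "gradual_vern_up",
    "late_vern_up": "late_vern_down",
    "late_vern_down": "late_vern_up",
    "long_day_up": "long_day_down",
    "long_day_down": "long_day_up",
}

#: labels admissible on a grid without mid/late cold points
SHORT_GRID_LABELS = frozenset(
    {"transient_stress_up", "transient_stress_down", "long_day_up",
     "long_day_down", "null_flat", "unclassified"}
)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and phase mapping for centroid classification.

    ``tau`` is the activation threshold in within-centroid SD units: a
    phase counts as responding when its standardized deviation from the
    baseline point reaches ``tau`` (and as quiet when it stays inside
    ``tau / 2``).  ``phase_map`` maps classifier roles (baseline, early,
    mid, late, long_day) to grid indices; by default it is derived from
    the grid.
    """

    tau: float = 1.0
    phase_map: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")

    def roles_for(self, grid: TimeGrid) -> dict[str, int]:
        roles = self.phase_map if self.phase_map is not None else grid.phase_roles()
        if "baseline" not in roles:
            raise ValueError("phase_map must include a 'baseline' role")
        return roles


def standardize_centroid(c: np.ndarray) -> np.ndarray:
    """Z-score a centroid: (c - mean) / SD (population SD).

    Constant centroids return the all-zero profile, which the classifier
    routes to ``null_flat``.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 1 or len(c) < 2:
        raise ValueError("centroid must be a 1-D vector of length >= 2")
    sd = c.std()
    if sd == 0:
        return np.zeros_like(c)
    return (c - c.mean()) / sd


def classify_centroid(
    c: np.ndarray, grid: TimeGrid, cfg: ClassifierConfig | None = None
) -> str:
    """Assign one expression-profile label to a centroid.

    Rules are evaluated on baseline-relative standardized deviations
    ``d_role = z[role] - z[baseline]`` in a fixed order (first match
    wins): transient stress up, cold acclimation, gradual vernalization
    up, late vernalization up, long-day up, then the four down-class
    mirrors in the same relative order.  Constant centroids are
    ``null_flat``; anything that matches no rule is ``unclassified``.
    Grids without mid/late cold points only admit the transient-stress
    and long-day classes.
    """
    cfg = cfg or ClassifierConfig()
    c = np.asarray(c, dtype=float)
    if len(c) != len(grid):
        raise ValueError(f"centroid length {len(c)} != grid length {len(grid)}")
    if np.ptp(c) == 0:
        return "null_flat"
    z = standardize_centroid(c)
    roles = cfg.roles_for(grid)
    tau = cfg.tau
    base = z[roles["baseline"]]

    def d(role: str) -> float | None:
        idx = roles.get(role)
        return None if idx is None else float(z[idx] - base)

    de, dm, dl, dld = d("early"), d("mid"), d("late"), d("long_day")
    full = dm is not None and dl is not None

    def quiet(x: float | None) -> bool:  # |d| < tau/2, vacuous if absent
        return x is None or abs(x) < tau / 2

    if de is not None and dld is not None:
        # --- up classes, fixed order ---
        if de >= tau and quiet(dm) and quiet(dl):
            return "transient_stress_up"
        if full and de >= tau and dm >= tau and dl >= tau and dld < tau / 2:
            return "cold_acclimation"
        if full and dl >= tau and dm >= tau / 2 and de < tau / 2 and dld >= tau / 2:
            return "gradual_vern_up"
        if full and dl >= tau and de < tau / 2 and dm < tau / 2:
            return "late_vern_up"
        if dld >= tau and abs(de) < tau / 2 and quiet(dm) and quiet(dl):
            return "long_day_up"
        # --- mirrored down classes ---
        if de <= -tau and quiet(dm) and quiet(dl):
            return "transient_stress_down"
        if full and dl <= -tau and dm <= -tau / 2 and de > -tau / 2 and dld <= -tau / 2:
            return "gradual_vern_down"
        if full and dl <= -tau and de > -tau / 2 and dm > -tau / 2:
            return "late_vern_down"
        if dld <= -tau and abs(de) < tau / 2 and quiet(dm) and quiet(dl):
            return "long_day_down"
    return "unclassified"


def classify_model(model, grid: TimeGrid, cfg: ClassifierConfig | None = None) -> pd.DataFrame:
    """Label every centroid of a fitted cluster model.

    Returns a table with one row per cluster: cluster id, assigned
    profile label, and cluster size.
    """
    cfg = cfg or ClassifierConfig()
    sizes = pd.Series(model.assignments).value_counts()
    rows = []
    for k in range(model.K):
        label = classify_centroid(model.centroids[k], grid, cfg)
        rows.append(
            {"cluster": k + 1, "label": label, "size": int(sizes.get(k + 1, 0))}
        )
    return pd.DataFrame(rows)


def label_summary(table: pd.DataFrame) -> pd.Series:
    """Count clusters per profile label (sums to K)."""
    return table["label"].value_counts()
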