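"""Sampling-time grids for the two-step floral-induction design.

Perennial ryegrass needs a *primary* induction (weeks of cold at short
days, i.e. vernalization) followed by a *secondary* induction (warmth and
long days) before it flowers.  Every stage of this package shares a
:class:`TimeGrid`: the ordered calendar days at which a tissue was
sampled, each tagged with the induction phase it belongs to.

Two grids ship as defaults, mirroring a typical design: leaves sampled
before vernalization, at 2 days, 4 weeks and 9 weeks of cold, and after 7
long days; meristem-enriched tissue sampled at 9 weeks of cold and after
1 and 7 long days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASES = ("pre_induction", "early_cold", "mid_cold", "late_cold", "long_day")
TISSUES = ("leaf", "meristem")

#: phase roles used by the profile classifier
PHASE_ROLES = ("baseline", "early", "mid", "late", "long_day")


@dataclass(frozen=True)
class TimeGrid:
    """Ordered calendar times (days) with phase labels for one tissue.

    Parameters
    ----------
    times
        Strictly increasing sampling days.
    phases
        One label per time point, drawn from ``PHASES``.
    tissue
        ``"leaf"`` or ``"meristem"``.
    """

    times: tuple[float, ...]
    phases: tuple[str, ...]
    tissue: str

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "phases", tuple(self.phases))
        if len(times) < 2:
            raise ValueError("a TimeGrid needs at least 2 time points")
        if len(times) != len(self.phases):
            raise ValueError(
                f"{len(times)} times but {len(self.phases)} phase labels"
            )
        if not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError(f"times must be strictly increasing, got {times}")
        bad = [p for p in self.phases if p not in PHASES]
        if bad:
            raise ValueError(f"unknown phase labels: {bad}; allowed: {PHASES}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def span(self) -> float:
        return self.times[-1] - self.times[0]

    def phase_roles(self) -> dict[str, int]:
        """Map classifier phase roles to grid indices.

        The first grid point is the baseline (the non-inductive reference
        state).  For the 5-point leaf grid the mapping is baseline/early/
        mid/late/long_day in order; 3-point meristem grids have no mid or
        late cold point and map baseline/early/long_day.
        """
        n = len(self)
        if n == 5:
            return {"baseline": 0, "early": 1, "mid": 2, "late": 3, "long_day": 4}
        if n == 3:
            return {"baseline": 0, "early": 1, "long_day": 2}
        # generic fallback: first = baseline, last = long_day, second = early
        roles = {"baseline": 0, "early": 1, "long_day": n - 1}
        if n >= 4:
            roles["late"] = n - 2
        if n >= 5:
            roles["mid"] = 2
        return roles


def leaf_grid() -> TimeGrid:
    """Default leaf grid: days {0, 2, 28, 63, 70}.

    Pre-vernalization, 2 days / 4 weeks / 9 weeks of cold, then 7 long
    days (the long-day phase starts at day 63).
    """
    return TimeGrid(
        times=(0.0, 2.0, 28.0, 63.0, 70.0),
        phases=("pre_induction", "early_cold", "mid_cold", "late_cold", "long_day"),
        tissue="leaf",
    )


def meristem_grid() -> TimeGrid:
    """Default enriched-meristem grid: days {63, 64, 70}.

    9 weeks of vernalization, then 1 and 7 long days.  The 9-week cold
    point serves as the baseline for profile classification.
    """
    return TimeGrid(
        times=(63.0, 64.0, 70.0),
        phases=("late_cold", "long_day", "long_day"),
        tissue="meristem",
    )
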