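"""Importance-performance analysis (IPA).

Each criterion is placed in a two-axis plane: *importance* (its global
weight from the preference elicitation) against *performance* (its mean
Likert satisfaction score).  Two thresholds split the plane into four
quadrants:

- **I — keep up the good work**: high importance, high performance;
- **II — possible overkill**: low importance, high performance;
- **III — low priority**: low importance, low performance;
- **IV — concentrate here**: high importance, low performance.

"High" means *at or above* the threshold.  Threshold strategies: grand mean
of each axis (default), median, the scale midpoint (3.0 for a 1-5 Likert
axis and 1/m for m equally-weighted criteria), or fixed user-supplied
values.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .instrument import Instrument
from .panel import RespondentPanel

__all__ = [
    "Thresholds",
    "IPAResult",
    "QUADRANT_LABELS",
    "mean_performance",
    "compute_thresholds",
    "classify_quadrants",
]

QUADRANT_LABELS = {
    "I": "keep up the good work",
    "II": "possible overkill",
    "III": "low priority",
    "IV": "concentrate here",
}

_STRATEGIES = ("grand_mean", "median", "scale_midpoint", "fixed")


@dataclasses.dataclass(frozen=True)
class Thresholds:
    strategy: str
    tau_importance: float
    tau_performance: float

    def __post_init__(self) -> None:
        if self.strategy not in _STRATEGIES:
            raise ValueError(f"unknown threshold strategy {self.strategy!r}")
        if self.tau_importance <= 0:
            raise ValueError("importance threshold must be positive")
        if self.strategy != "fixed" and not (1.0 <= self.tau_performance <= 5.0):
            raise ValueError("performance threshold must lie on the Likert scale [1, 5]")


@dataclasses.dataclass
class IPAResult:
    """Per-criterion (importance, performance, quadrant) plus thresholds used."""

    table: pd.DataFrame  # columns: crit_id, importance, performance, quadrant
    thresholds: Thresholds

    def quadrant_counts(self) -> dict[str, int]:
        counts = self.table["quadrant"].value_counts().to_dict()
        return {q: int(counts.get(q, 0)) for q in ("I", "II", "III", "IV")}


def mean_performance(
    panel: RespondentPanel,
    reverse_code: bool = False,
) -> pd.Series:
    """Mean Likert score per criterion, averaged over respondents.

    With ``reverse_code=True``, ratings of reverse-worded items are recoded
    as ``6 - x`` before averaging, so that higher always means more
    satisfied.  The default leaves ratings as collected.
    """
    wide = panel.ratings_frame().astype(float)
    if reverse_code:
        for cid in panel.instrument.reverse_worded_ids():
            wide[cid] = 6.0 - wide[cid]
    perf = wide.mean(axis=0)
    perf.name = "performance"
    return perf


def compute_thresholds(
    importance: Sequence[float],
    performance: Sequence[float],
    strategy: str = "grand_mean",
    tau_importance: float | None = None,
    tau_performance: float | None = None,
) -> Thresholds:
    """Axis-crossing values for the quadrant split.

    ``scale_midpoint`` uses 3.0 on the 1-5 performance axis and ``1/m`` on
    the importance axis (the weight every criterion would get if all m were
    equal).  ``fixed`` echoes the supplied values and requires both.
    """
    imp = np.asarray(importance, dtype=float)
    perf = np.asarray(performance, dtype=float)
    if imp.size == 0 or perf.size == 0:
        raise ValueError("importance and performance lists must be nonempty")
    if strategy == "grand_mean":
        return Thresholds(strategy, float(imp.mean()), float(perf.mean()))
    if strategy == "median":
        return Thresholds(strategy, float(np.median(imp)), float(np.median(perf)))
    if strategy == "scale_midpoint":
        return Thresholds(strategy, 1.0 / imp.size, 3.0)
    if strategy == "fixed":
        if tau_importance is None or tau_performance is None:
            raise ValueError("fixed strategy requires both tau_importance and tau_performance")
        return Thresholds(strategy, float(tau_importance), float(tau_performance))
    raise ValueError(f"unknown threshold strategy {strategy!r}")


def classify_quadrants(
    criterion_ids: Sequence[str],
    importance: Sequence[float],
    performance: Sequence[float],
    thresholds: Thresholds,
) -> IPAResult:
    """Assign every criterion to exactly one quadrant.

    A value equal to its threshold counts as "high", so a point exactly at
    both thresholds lands in quadrant I.
    """
    imp = np.asarray(importance, dtype=float)
    perf = np.asarray(performance, dtype=float)
    if not (len(criterion_ids) == imp.size == perf.size):
        raise ValueError("criterion_ids, importance and performance must have equal length")
    hi_imp = imp >= thresholds.tau_importance
    hi_perf = perf >= thresholds.tau_performance
    quad = np.where(
        hi_imp, np.where(hi_perf, "I", "IV"), np.where(hi_perf, "II", "III")
    )
    table = pd.DataFrame(
        {
            "crit_id": list(criterion_ids),
            "importance": imp,
            "performance": perf,
            "quadrant": quad,
        }
    )
    return IPAResult(table=table, thresholds=thresholds)


def plot_quadrants(result: IPAResult, ax=None):
    """Optional scatter of the IPA plane with threshold lines.

    Requires matplotlib; importance on the x axis, performance on the y
    axis, criteria annotated by id.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    t = result.table
    ax.scatter(t["importance"], t["performance"], s=18, color="tab:blue")
    for _, row in t.iterrows():
        ax.annotate(row["crit_id"], (row["importance"], row["performance"]),
                    textcoords="offset points", xytext=(4, 3), fontsize=8)
    ax.axvline(result.thresholds.tau_importance, color="grey", lw=1, ls="--")
    ax.axhline(result.thresholds.tau_performance, color="grey", lw=1, ls="--")
    ax.set_xlabel("importance (global weight)")
    ax.set_ylabel("performance (mean Likert score)")
    return ax
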