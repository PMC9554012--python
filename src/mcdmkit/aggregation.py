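"""Group aggregation of expert weights, global composition and stability.

Per-respondent weight vectors are averaged arithmetically into group
weights.  Dimension weights and within-dimension criterion weights compose
multiplicatively into global weights (``w_global = w_dim * w_crit|dim``),
which sum to 1 across the whole instrument.  Panel stability is summarized
by the confidence level (CL): the mean relative change of the weights when
one respondent is removed, with a conventional 5% pass threshold.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cfpr import WeightVector
from .instrument import Instrument

__all__ = [
    "WeightTable",
    "ConfidenceStat",
    "aggregate_expert_weights",
    "rank_weights",
    "compute_global_weights",
    "confidence_level",
    "leave_one_out_confidence",
]


def aggregate_expert_weights(vectors: Sequence[WeightVector]) -> WeightVector:
    """Element-wise arithmetic mean of per-respondent weight vectors.

    Each input sums to 1, so the mean does too.  All vectors must belong to
    the same group and have equal length.
    """
    if len(vectors) == 0:
        raise ValueError("cannot aggregate an empty list of weight vectors")
    k = vectors[0].k
    gid = vectors[0].group_id
    for v in vectors[1:]:
        if v.k != k:
            raise ValueError(f"group {gid!r}: weight vectors of unequal length ({v.k} vs {k})")
    mean = np.mean([v.as_array() for v in vectors], axis=0)
    return WeightVector(group_id=gid, weights=tuple(mean))


def rank_weights(values: Sequence[float]) -> list[int]:
    """Descending competition ranks: the largest value gets rank 1.

    Ties share the smallest rank of the tied block ("1224" style); tied
    entries keep their input (instrument) order in any listing.
    """
    if len(values) == 0:
        raise ValueError("cannot rank an empty list")
    return [int(r) for r in rankdata([-v for v in values], method="min")]


@dataclasses.dataclass
class WeightTable:
    """Dimension, local-criterion and global weights with ranks.

    ``dimensions``: one row per dimension (dim_id, dim_weight, dim_rank);
    ``criteria``: one row per criterion (dim_id, crit_id, crit_weight,
    crit_rank within its dimension, global_weight, global_rank).
    """

    dimensions: pd.DataFrame
    criteria: pd.DataFrame

    def global_weights(self) -> pd.Series:
        return self.criteria.set_index("crit_id")["global_weight"]

    def check(self, atol: float = 1e-9) -> None:
        if abs(self.dimensions["dim_weight"].sum() - 1.0) > atol:
            raise ValueError("dimension weights do not sum to 1")
        for dim_id, block in self.criteria.groupby("dim_id", sort=False):
            if abs(block["crit_weight"].sum() - 1.0) > atol:
                raise ValueError(f"local weights in dimension {dim_id!r} do not sum to 1")
        if abs(self.criteria["global_weight"].sum() - 1.0) > atol:
            raise ValueError("global weights do not sum to 1")


def compute_global_weights(
    instrument: Instrument,
    dim_weights: WeightVector,
    crit_weights: Sequence[WeightVector],
) -> WeightTable:
    """Compose dimension and within-dimension weights into a full table.

    ``crit_weights`` holds one vector per dimension, in instrument order;
    global weight of criterion c in dimension d is ``w_d * w_{c|d}``.  Ranks
    are recomputed from full precision, never from rounded values.
    """
    if dim_weights.k != instrument.n_dimensions:
        raise ValueError(
            f"dimension weight vector has length {dim_weights.k}, "
            f"instrument has {instrument.n_dimensions} dimensions"
        )
    if len(crit_weights) != instrument.n_dimensions:
        raise ValueError("need one criterion weight vector per dimension")

    dim_rows = pd.DataFrame(
        {
            "dim_id": instrument.dimension_ids,
            "dim_weight": list(dim_weights.weights),
        }
    )
    dim_rows["dim_rank"] = rank_weights(dim_rows["dim_weight"])

    crit_rows = []
    for d, wv, w_d in zip(instrument.dimensions, crit_weights, dim_weights.weights):
        if wv.k != len(d.criteria):
            raise ValueError(
                f"dimension {d.id!r}: weight vector length {wv.k} != "
                f"{len(d.criteria)} criteria"
            )
        local_ranks = rank_weights(wv.weights)
        for c, w_c, r in zip(d.criteria, wv.weights, local_ranks):
            crit_rows.append(
                {
                    "dim_id": d.id,
                    "crit_id": c.id,
                    "crit_weight": w_c,
                    "crit_rank": r,
                    "global_weight": w_d * w_c,
                }
            )
    crit = pd.DataFrame(crit_rows)
    crit["global_rank"] = rank_weights(crit["global_weight"])
    table = WeightTable(dimensions=dim_rows, criteria=crit)
    table.check()
    return table


@dataclasses.dataclass(frozen=True)
class ConfidenceStat:
    """Leave-one-respondent stability of aggregated weights, in percent.

    ``value`` is ``CL = (1/k) * sum_i |w_i^(n) - w_i^(n-1)| / w_i^(n) * 100``
    where ``w^(n)`` aggregates all respondents and ``w^(n-1)`` all but one.
    """

    n: int
    value: float
    threshold: float = 5.0
    variant: str = "drop_last"

    @property
    def passed(self) -> bool:
        return self.value < self.threshold


def leave_one_out_confidence(
    aggregate_fn,
    n: int,
    threshold: float = 5.0,
    variant: str = "drop_last",
) -> ConfidenceStat:
    """Confidence level of aggregated weights under respondent removal.

    ``aggregate_fn(indices)`` must return the aggregated weight vector for
    the given subset of respondent indices (0..n-1) — whatever aggregation
    the caller reports (for the full pipeline, group means composed into
    global weights).  Variants:

    - ``"drop_last"``: w^(n-1) aggregates the first n-1 respondents;
    - ``"loo_mean"`` / ``"loo_max"``: mean / max CL over all n single
      leave-one-out subpanels.
    """
    if n < 2:
        raise ValueError(f"confidence level needs at least 2 respondents, got {n}")
    full = np.asarray(aggregate_fn(list(range(n))), dtype=float)

    def cl_against(indices: list[int]) -> float:
        reduced = np.asarray(aggregate_fn(indices), dtype=float)
        return float(np.mean(np.abs(full - reduced) / full) * 100.0)

    if variant == "drop_last":
        value = cl_against(list(range(n - 1)))
    elif variant in ("loo_mean", "loo_max"):
        cls = [cl_against([j for j in range(n) if j != i]) for i in range(n)]
        value = float(np.mean(cls)) if variant == "loo_mean" else float(np.max(cls))
    else:
        raise ValueError(f"unknown confidence variant {variant!r}")
    return ConfidenceStat(n=n, value=value, threshold=threshold, variant=variant)


def confidence_level(
    respondent_weights: Sequence[Sequence[float]],
    threshold: float = 5.0,
    variant: str = "drop_last",
) -> ConfidenceStat:
    """Confidence level when aggregation is a plain element-wise mean.

    ``respondent_weights`` is one weight vector per respondent, in file
    order.  Convenience wrapper over :func:`leave_one_out_confidence`.
    """
    w = np.asarray(respondent_weights, dtype=float)
    if w.ndim != 2:
        raise ValueError("expected one weight vector per respondent")
    return leave_one_out_confidence(
        lambda idx: w[list(idx)].mean(axis=0),
        n=w.shape[0],
        threshold=threshold,
        variant=variant,
    )
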