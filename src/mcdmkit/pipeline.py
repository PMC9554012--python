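"""End-to-end orchestration: panel -> weights -> aggregation -> IPA.

Stages are pure: no step mutates the instrument or the panel, and each
respondent contributes one weight vector per comparison group.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .aggregation import (
    ConfidenceStat,
    WeightTable,
    aggregate_expert_weights,
    compute_global_weights,
    leave_one_out_confidence,
)
from .cfpr import WeightVector, chain_weights
from .instrument import DIMENSION_GROUP, Instrument
from .ipa import IPAResult, classify_quadrants, compute_thresholds, mean_performance
from .panel import RespondentPanel

__all__ = ["PipelineConfig", "PipelineResult", "respondent_weights",
           "respondent_global_weights", "panel_weight_table", "run_pipeline"]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Knobs for one pipeline run.

    ``threshold_strategy`` picks the IPA axis-crossing rule; ``fixed``
    requires both tau values.  ``reverse_code`` recodes reverse-worded items
    as ``6 - x`` before computing performance (off by default: performance
    is reported on the raw ratings as collected).
    """

    threshold_strategy: str = "grand_mean"
    tau_importance: float | None = None
    tau_performance: float | None = None
    reverse_code: bool = False
    confidence_threshold: float = 5.0
    confidence_variant: str = "drop_last"


@dataclasses.dataclass
class PipelineResult:
    weight_table: WeightTable
    ipa: IPAResult
    confidence: ConfidenceStat | None


def respondent_weights(panel: RespondentPanel) -> dict[str, dict[str, WeightVector]]:
    """Per-respondent weight vectors for every comparison group.

    Returns ``{respondent_id: {group_id: WeightVector}}``; each vector comes
    from the respondent's judgment chain via completion, rescaling and
    row-sum normalization.
    """
    out: dict[str, dict[str, WeightVector]] = {}
    group_ids = list(panel.instrument.groups())
    for rid in panel.respondent_ids:
        out[rid] = {gid: chain_weights(panel.fuzzy_chain(rid, gid)) for gid in group_ids}
    return out


def respondent_global_weights(
    instrument: Instrument,
    weights: dict[str, dict[str, WeightVector]],
) -> np.ndarray:
    """Global weight vector (one row per respondent, instrument order)."""
    rows = []
    for per_group in weights.values():
        dim_w = dict(zip(instrument.dimension_ids, per_group[DIMENSION_GROUP].weights))
        row = []
        for d in instrument.dimensions:
            for c_id, w_c in zip([c.id for c in d.criteria], per_group[d.id].weights):
                row.append(dim_w[d.id] * w_c)
        rows.append(row)
    return np.asarray(rows, dtype=float)


def panel_weight_table(
    instrument: Instrument, weights: dict[str, dict[str, WeightVector]]
) -> WeightTable:
    """Aggregate per-respondent group weights and compose the weight table."""
    by_group: dict[str, list[WeightVector]] = {}
    for per_group in weights.values():
        for gid, wv in per_group.items():
            by_group.setdefault(gid, []).append(wv)
    dim_mean = aggregate_expert_weights(by_group[DIMENSION_GROUP])
    crit_means = [aggregate_expert_weights(by_group[d.id]) for d in instrument.dimensions]
    return compute_global_weights(instrument, dim_mean, crit_means)


def run_pipeline(
    instrument: Instrument,
    panel: RespondentPanel,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run elicitation, aggregation, composition and IPA on a full panel.

    The confidence statistic is computed on the per-respondent *global*
    weights (the default weight set); it is omitted for a single-respondent
    panel, where leave-one-out is undefined.
    """
    config = config or PipelineConfig()
    panel.validate()

    weights = respondent_weights(panel)
    table = panel_weight_table(instrument, weights)

    confidence = None
    if panel.n >= 2:
        # CL compares the same composed aggregate that the weight table
        # reports (group means composed into globals), with and without the
        # removed respondent
        rids = panel.respondent_ids

        def composed_global(indices):
            sub = {rids[i]: weights[rids[i]] for i in indices}
            sub_table = panel_weight_table(instrument, sub)
            return sub_table.criteria["global_weight"].to_numpy()

        confidence = leave_one_out_confidence(
            composed_global,
            n=panel.n,
            threshold=config.confidence_threshold,
            variant=config.confidence_variant,
        )

    perf = mean_performance(panel, reverse_code=config.reverse_code)
    crit_ids = instrument.criterion_ids
    importance = table.global_weights().reindex(crit_ids).to_numpy()
    performance = perf.reindex(crit_ids).to_numpy()
    thresholds = compute_thresholds(
        importance,
        performance,
        strategy=config.threshold_strategy,
        tau_importance=config.tau_importance,
        tau_performance=config.tau_performance,
    )
    ipa = classify_quadrants(crit_ids, importance, performance, thresholds)
    return PipelineResult(weight_table=table, ipa=ipa, confidence=confidence)
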