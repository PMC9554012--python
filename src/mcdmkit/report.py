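"""TSV report writers for weight and IPA tables.

Weights and performance are printed with 4 decimals using round-half-up
(matching the usual print convention for these tables); full precision is
kept in memory — only the serialized reports are rounded.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .aggregation import ConfidenceStat, WeightTable
from .ipa import IPAResult

__all__ = ["round_half_up", "write_weight_table", "write_ipa_table",
           "read_weight_table", "read_ipa_table"]

WEIGHT_COLUMNS = ["dimension", "dim_weight", "dim_rank", "criterion",
                  "crit_weight", "crit_rank", "global_weight", "global_rank"]
IPA_COLUMNS = ["criterion", "importance", "performance", "quadrant"]


def round_half_up(x: float, decimals: int = 4) -> float:
    """Decimal round-half-up (0.00005 -> 0.0001), unlike banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x: float, decimals: int = 4) -> str:
    return f"{round_half_up(x, decimals):.{decimals}f}"


def write_weight_table(
    table: WeightTable,
    path: str | Path,
    confidence: ConfidenceStat | None = None,
) -> None:
    """Write one row per criterion with its dimension block repeated.

    If a confidence statistic is given it is appended as a ``#`` footer
    line (readers skip comment lines).
    """
    path = Path(path)
    dims = table.dimensions.set_index("dim_id")
    lines = ["\t".join(WEIGHT_COLUMNS)]
    for row in table.criteria.itertuples(index=False):
        d = dims.loc[row.dim_id]
        lines.append(
            "\t".join(
                [
                    row.dim_id,
                    _fmt(d["dim_weight"]),
                    str(int(d["dim_rank"])),
                    row.crit_id,
                    _fmt(row.crit_weight),
                    str(int(row.crit_rank)),
                    _fmt(row.global_weight),
                    str(int(row.global_rank)),
                ]
            )
        )
    if confidence is not None:
        lines.append(
            f"# confidence_level_pct={confidence.value:.4f}\t"
            f"threshold_pct={confidence.threshold:g}\t"
            f"passed={confidence.passed}\tn={confidence.n}\tvariant={confidence.variant}"
        )
    path.write_text("\n".join(lines) + "\n")


def write_ipa_table(result: IPAResult, path: str | Path) -> None:
    """Write per-criterion importance, performance and quadrant (I..IV)."""
    path = Path(path)
    lines = ["\t".join(IPA_COLUMNS)]
    for row in result.table.itertuples(index=False):
        lines.append(
            "\t".join([row.crit_id, _fmt(row.importance), _fmt(row.performance), row.quadrant])
        )
    t = result.thresholds
    lines.append(
        f"# strategy={t.strategy}\ttau_importance={t.tau_importance:.4f}\t"
        f"tau_performance={t.tau_performance:.4f}"
    )
    path.write_text("\n".join(lines) + "\n")


def read_weight_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_ipa_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
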