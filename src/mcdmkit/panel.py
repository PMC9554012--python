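"""Respondent panels: pairwise judgments and Likert ratings for an instrument.

Long-format CSV on disk, one record per row.  Validation is strict and no
imputation is performed: every respondent must supply exactly ``k - 1``
adjacent judgments per comparison group of size ``k`` and exactly one rating
per criterion, or the panel is rejected with an error naming the respondent
and field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .cfpr import FuzzyChain, ratio_to_fuzzy
from .instrument import Instrument

__all__ = ["JudgmentRecord", "RatingRecord", "RespondentPanel", "PanelError",
           "load_panel", "write_panel"]

JUDGMENT_COLUMNS = ["respondent_id", "group_id", "left_id", "right_id", "value", "scale"]
RATING_COLUMNS = ["respondent_id", "criterion_id", "rating"]

_SCALES = ("fuzzy", "saaty")


class PanelError(ValueError):
    """Invalid or incomplete panel data."""


@dataclasses.dataclass(frozen=True)
class JudgmentRecord:
    """One adjacent pairwise comparison by one respondent.

    ``scale`` is ``"fuzzy"`` (value on [0, 1]) or ``"saaty"`` (ratio on
    [1/9, 9], converted downstream via the log transform).
    """

    respondent_id: str
    group_id: str
    left_id: str
    right_id: str
    value: float
    scale: str = "fuzzy"

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise PanelError(
                f"respondent {self.respondent_id!r}: unknown judgment scale {self.scale!r}"
            )
        lo, hi = (0.0, 1.0) if self.scale == "fuzzy" else (1.0 / 9.0, 9.0)
        if not (lo <= self.value <= hi):
            raise PanelError(
                f"respondent {self.respondent_id!r}: judgment {self.left_id}~{self.right_id} "
                f"value {self.value} outside {self.scale} range [{lo:g}, {hi:g}]"
            )

    @property
    def fuzzy_value(self) -> float:
        return self.value if self.scale == "fuzzy" else ratio_to_fuzzy(self.value)


@dataclasses.dataclass(frozen=True)
class RatingRecord:
    """One 5-point Likert rating (1 = strongly disagree ... 5 = strongly agree)."""

    respondent_id: str
    criterion_id: str
    rating: int

    def __post_init__(self) -> None:
        if self.rating not in (1, 2, 3, 4, 5):
            raise PanelError(
                f"respondent {self.respondent_id!r}: rating for {self.criterion_id!r} "
                f"must be an integer in 1..5, got {self.rating!r}"
            )


@dataclasses.dataclass
class RespondentPanel:
    """A complete panel of judgments and ratings for one instrument."""

    instrument: Instrument
    judgments: list[JudgmentRecord]
    ratings: list[RatingRecord]

    @property
    def respondent_ids(self) -> list[str]:
        """Respondent ids in order of first appearance (file order)."""
        seen: dict[str, None] = {}
        for rec in self.judgments:
            seen.setdefault(rec.respondent_id, None)
        for rec in self.ratings:
            seen.setdefault(rec.respondent_id, None)
        return list(seen)

    @property
    def n(self) -> int:
        return len(self.respondent_ids)

    def validate(self) -> None:
        """Enforce completeness, chain adjacency and id consistency."""
        groups = self.instrument.groups()
        adjacent = {
            (members[i], members[i + 1]): gid
            for gid, members in groups.items()
            for i in range(len(members) - 1)
        }
        crit_ids = set(self.instrument.criterion_ids)

        per_resp_pairs: dict[str, set[tuple[str, str]]] = {}
        for rec in self.judgments:
            if rec.group_id not in groups:
                raise PanelError(
                    f"respondent {rec.respondent_id!r}: unknown group id {rec.group_id!r}"
                )
            pair = (rec.left_id, rec.right_id)
            if adjacent.get(pair) != rec.group_id:
                raise PanelError(
                    f"respondent {rec.respondent_id!r}: non-adjacent pair "
                    f"{rec.left_id}~{rec.right_id} in group {rec.group_id!r} "
                    f"(comparisons must follow the instrument chain order)"
                )
            pairs = per_resp_pairs.setdefault(rec.respondent_id, set())
            if pair in pairs:
                raise PanelError(
                    f"respondent {rec.respondent_id!r}: duplicate judgment for "
                    f"{rec.left_id}~{rec.right_id}"
                )
            pairs.add(pair)

        per_resp_crit: dict[str, set[str]] = {}
        for rec in self.ratings:
            if rec.criterion_id not in crit_ids:
                raise PanelError(
                    f"respondent {rec.respondent_id!r}: unknown criterion id "
                    f"{rec.criterion_id!r}"
                )
            crits = per_resp_crit.setdefault(rec.respondent_id, set())
            if rec.criterion_id in crits:
                raise PanelError(
                    f"respondent {rec.respondent_id!r}: duplicate rating for "
                    f"{rec.criterion_id!r}"
                )
            crits.add(rec.criterion_id)

        if self.n == 0:
            raise PanelError("panel contains no respondents")
        required_pairs = set(adjacent)
        for rid in self.respondent_ids:
            missing_pairs = required_pairs - per_resp_pairs.get(rid, set())
            if missing_pairs:
                a, b = sorted(missing_pairs)[0]
                raise PanelError(
                    f"respondent {rid!r}: missing judgment for pair {a}~{b} "
                    f"(and {len(missing_pairs) - 1} more)"
                )
            missing_crit = crit_ids - per_resp_crit.get(rid, set())
            if missing_crit:
                raise PanelError(
                    f"respondent {rid!r}: missing rating for criterion "
                    f"{sorted(missing_crit)[0]!r}"
                    + (f" (and {len(missing_crit) - 1} more)" if len(missing_crit) > 1 else "")
                )

    def fuzzy_chain(self, respondent_id: str, group_id: str) -> FuzzyChain:
        """The respondent's judgment chain for one group, on the fuzzy scale."""
        members = self.instrument.groups()[group_id]
        by_pair = {
            (rec.left_id, rec.right_id): rec
            for rec in self.judgments
            if rec.respondent_id == respondent_id and rec.group_id == group_id
        }
        values = []
        for i in range(len(members) - 1):
            rec = by_pair.get((members[i], members[i + 1]))
            if rec is None:
                raise PanelError(
                    f"respondent {respondent_id!r}: missing judgment for pair "
                    f"{members[i]}~{members[i + 1]}"
                )
            values.append(rec.fuzzy_value)
        return FuzzyChain(group_id=group_id, values=tuple(values))

    def ratings_frame(self) -> pd.DataFrame:
        """Ratings as a (respondent x criterion) wide DataFrame."""
        df = pd.DataFrame(
            [(r.respondent_id, r.criterion_id, r.rating) for r in self.ratings],
            columns=RATING_COLUMNS,
        )
        wide = df.pivot(index="respondent_id", columns="criterion_id", values="rating")
        return wide.reindex(index=self.respondent_ids, columns=self.instrument.criterion_ids)


def _require_columns(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing required columns {missing}")


def load_panel(
    instrument: Instrument,
    judgments_path: str | Path,
    ratings_path: str | Path,
) -> RespondentPanel:
    """Read long-format judgment and rating CSVs into a validated panel."""
    judgments_path, ratings_path = Path(judgments_path), Path(ratings_path)
    jdf = pd.read_csv(judgments_path, dtype=str)
    rdf = pd.read_csv(ratings_path, dtype=str)
    _require_columns(jdf, JUDGMENT_COLUMNS, judgments_path)
    _require_columns(rdf, RATING_COLUMNS, ratings_path)

    judgments = []
    for row in jdf.itertuples(index=False):
        try:
            value = float(row.value)
        except ValueError as exc:
            raise PanelError(
                f"respondent {row.respondent_id!r}: non-numeric judgment value {row.value!r}"
            ) from exc
        judgments.append(
            JudgmentRecord(
                respondent_id=str(row.respondent_id),
                group_id=str(row.group_id),
                left_id=str(row.left_id),
                right_id=str(row.right_id),
                value=value,
                scale=str(row.scale),
            )
        )
    ratings = []
    for row in rdf.itertuples(index=False):
        try:
            rating = int(row.rating)
        except ValueError as exc:
            raise PanelError(
                f"respondent {row.respondent_id!r}: non-integer rating {row.rating!r} "
                f"for {row.criterion_id!r}"
            ) from exc
        ratings.append(
            RatingRecord(
                respondent_id=str(row.respondent_id),
                criterion_id=str(row.criterion_id),
                rating=rating,
            )
        )
    panel = RespondentPanel(instrument=instrument, judgments=judgments, ratings=ratings)
    panel.validate()
    return panel


def write_panel(
    panel: RespondentPanel,
    judgments_path: str | Path,
    ratings_path: str | Path,
) -> None:
    """Write a panel back to the long-format CSV schemas."""
    jdf = pd.DataFrame(
        [dataclasses.astuple(r) for r in panel.judgments], columns=JUDGMENT_COLUMNS
    )
    rdf = pd.DataFrame(
        [dataclasses.astuple(r) for r in panel.ratings], columns=RATING_COLUMNS
    )
    jdf.to_csv(judgments_path, index=False)
    rdf.to_csv(ratings_path, index=False)
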