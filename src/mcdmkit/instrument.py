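"""Survey-instrument definitions: a hierarchy of dimensions and criteria.

The order of dimensions and of criteria within a dimension is significant —
it fixes the adjacent-pair comparison chains used for weight elicitation.
"""

from __future__ import annotations

import json
from pathlib import Path

import pydantic
import yaml

__all__ = ["Criterion", "Dimension", "Instrument", "InstrumentError",
           "load_instrument", "save_instrument", "DIMENSION_GROUP"]

#: group id for the chain that compares the dimensions among themselves
DIMENSION_GROUP = "DIMS"


class InstrumentError(ValueError):
    """Invalid instrument definition."""


class Criterion(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(frozen=True)

    id: str
    label: str = ""
    reverse_worded: bool = False


class Dimension(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(frozen=True)

    id: str
    label: str = ""
    criteria: tuple[Criterion, ...]

    @pydantic.field_validator("criteria")
    @classmethod
    def _non_empty(cls, v: tuple[Criterion, ...]) -> tuple[Criterion, ...]:
        if len(v) == 0:
            raise ValueError("dimension must contain at least one criterion")
        return v


class Instrument(pydantic.BaseModel):
    """An ordered hierarchy of dimensions, each holding ordered criteria."""

    model_config = pydantic.ConfigDict(frozen=True)

    name: str
    dimensions: tuple[Dimension, ...]

    @pydantic.model_validator(mode="after")
    def _validate_ids(self) -> "Instrument":
        if len(self.dimensions) == 0:
            raise ValueError("instrument has no dimensions")
        dim_ids = [d.id for d in self.dimensions]
        crit_ids = [c.id for d in self.dimensions for c in d.criteria]
        for name, ids in (("dimension", dim_ids), ("criterion", crit_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        clash = set(dim_ids) & set(crit_ids)
        if clash:
            raise ValueError(f"ids used as both dimension and criterion: {sorted(clash)}")
        if DIMENSION_GROUP in set(dim_ids) | set(crit_ids):
            raise ValueError(f"id {DIMENSION_GROUP!r} is reserved for the dimension chain")
        return self

    # -- lookups ---------------------------------------------------------

    @property
    def dimension_ids(self) -> list[str]:
        return [d.id for d in self.dimensions]

    @property
    def criterion_ids(self) -> list[str]:
        return [c.id for d in self.dimensions for c in d.criteria]

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    @property
    def n_criteria(self) -> int:
        return len(self.criterion_ids)

    def dimension(self, dim_id: str) -> Dimension:
        for d in self.dimensions:
            if d.id == dim_id:
                return d
        raise KeyError(dim_id)

    def dimension_of(self, criterion_id: str) -> str:
        """Id of the dimension containing ``criterion_id``."""
        for d in self.dimensions:
            if any(c.id == criterion_id for c in d.criteria):
                return d.id
        raise KeyError(criterion_id)

    def groups(self) -> dict[str, list[str]]:
        """Comparison groups: the dimension chain plus one chain per dimension.

        Each value is the ordered member-id list; adjacent pairs in that
        order are the elicited comparisons.
        """
        out = {DIMENSION_GROUP: self.dimension_ids}
        for d in self.dimensions:
            out[d.id] = [c.id for c in d.criteria]
        return out

    def reverse_worded_ids(self) -> list[str]:
        return [c.id for d in self.dimensions for c in d.criteria if c.reverse_worded]

    def to_dict(self) -> dict:
        # json mode so tuples become lists (YAML/JSON serializable)
        return self.model_dump(mode="json")


def load_instrument(path: str | Path) -> Instrument:
    """Load and validate an instrument from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise InstrumentError(f"instrument file not found: {path}")
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(path.read_text())
        else:
            raw = yaml.safe_load(path.read_text())
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise InstrumentError(f"cannot parse instrument file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise InstrumentError(f"instrument file {path} must contain a mapping at top level")
    try:
        return Instrument.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise InstrumentError(f"invalid instrument in {path}: {exc}") from exc


def save_instrument(instrument: Instrument, path: str | Path) -> None:
    """Write an instrument back to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = instrument.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True))
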