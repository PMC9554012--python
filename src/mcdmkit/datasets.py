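"""Bundled instrument and reference tables.

``load_hhnjs`` returns the 30-item / 8-dimension Home Healthcare Nurse Job
Satisfaction Scale.  The two reference tables carry the published weight
and importance-performance results from a 31-nurse panel evaluated with
this instrument; they serve as regression anchors and as realistic default
parameters for the synthetic generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .instrument import Instrument, load_instrument

__all__ = ["load_hhnjs", "load_reference_weights", "load_reference_ipa"]


def _data_path(name: str):
    return resources.files("mcdmkit.data").joinpath(name)


def load_hhnjs() -> Instrument:
    """The HHNJS instrument: 8 dimensions, 30 Likert items."""
    with resources.as_file(_data_path("hhnjs.yaml")) as p:
        return load_instrument(p)


def load_reference_weights() -> pd.DataFrame:
    """Published HHNJS weights: one row per criterion.

    Columns: dimension, dim_weight, dim_rank, criterion, crit_weight,
    crit_rank, global_weight, global_rank (weights rounded to 4 decimals as
    printed).
    """
    with resources.as_file(_data_path("hhnjs_reference_weights.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_reference_ipa() -> pd.DataFrame:
    """Published HHNJS IPA results: criterion, importance, performance, quadrant."""
    with resources.as_file(_data_path("hhnjs_reference_ipa.tsv")) as p:
        return pd.read_csv(p, sep="\t")
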