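import numpy as np
import pytest
from hypothesis import settings

import mcdmkit as mk

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def hhnjs():
    return mk.load_hhnjs()


@pytest.fixture(scope="session")
def reference_weights():
    return mk.load_reference_weights()


@pytest.fixture(scope="session")
def reference_ipa():
    return mk.load_reference_ipa()


@pytest.fixture
def toy_instrument():
    """Two dimensions (2 + 3 criteria) — smallest shape with every chain kind."""
    return mk.Instrument.model_validate(
        {
            "name": "toy",
            "dimensions": [
                {"id": "D1", "label": "first", "criteria": [
                    {"id": "D11", "label": "a"}, {"id": "D12", "label": "b"}]},
                {"id": "D2", "label": "second", "criteria": [
                    {"id": "D21", "label": "c"}, {"id": "D22", "label": "d"},
                    {"id": "D23", "label": "e"}]},
            ],
        }
    )


def build_panel(instrument, chains_by_respondent, ratings_by_respondent):
    """Assemble a validated RespondentPanel from fuzzy chain values and ratings.

    ``chains_by_respondent``: {rid: {group_id: [p_12, p_23, ...]}};
    ``ratings_by_respondent``: {rid: {criterion_id: rating}}.
    """
    groups = instrument.groups()
    judgments, ratings = [], []
    for rid, chains in chains_by_respondent.items():
        for gid, values in chains.items():
            members = groups[gid]
            for i, v in enumerate(values):
                judgments.append(
                    mk.JudgmentRecord(
                        respondent_id=rid, group_id=gid,
                        left_id=members[i], right_id=members[i + 1],
                        value=float(v), scale="fuzzy",
                    )
                )
    for rid, rmap in ratings_by_respondent.items():
        for cid, rating in rmap.items():
            ratings.append(
                mk.RatingRecord(respondent_id=rid, criterion_id=cid, rating=int(rating))
            )
    panel = mk.RespondentPanel(instrument=instrument, judgments=judgments, ratings=ratings)
    panel.validate()
    return panel


@pytest.fixture
def uniform_toy_panel(toy_instrument):
    """Two identical, fully indifferent respondents rating everything 4."""
    groups = toy_instrument.groups()
    chains = {gid: [0.5] * (len(m) - 1) for gid, m in groups.items()}
    crits = toy_instrument.criterion_ids
    return build_panel(
        toy_instrument,
        {"r1": chains, "r2": chains},
        {"r1": {c: 4 for c in crits}, "r2": {c: 4 for c in crits}},
    )


def oracle_chain_weights(values):
    """Independent weight oracle: solve the transitivity equations directly.

    Sets up the linear system over the upper-triangle unknowns — the elicited
    chain entries plus ``p_ij + p_jl - p_il = 0.5`` for every triple — solves
    it by least squares, mirrors by reciprocity, rescales into [0, 1] and
    normalizes row sums.  Shares no code with the completion routine.
    """
    k = len(values) + 1
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    idx = {p: t for t, p in enumerate(pairs)}
    rows, rhs = [], []
    for i, v in enumerate(values):
        row = [0.0] * len(pairs)
        row[idx[(i, i + 1)]] = 1.0
        rows.append(row)
        rhs.append(v)
    for i in range(k):
        for j in range(i + 1, k):
            for l in range(j + 1, k):
                row = [0.0] * len(pairs)
                row[idx[(i, j)]] += 1.0
                row[idx[(j, l)]] += 1.0
                row[idx[(i, l)]] -= 1.0
                rows.append(row)
                rhs.append(0.5)
    sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    p = np.full((k, k), 0.5)
    for (i, j), t in idx.items():
        p[i, j] = sol[t]
        p[j, i] = 1.0 - sol[t]
    a = max(0.0, p.max() - 1.0)
    if a > 0:
        p = (p + a) / (1.0 + 2.0 * a)
    row_sums = p.sum(axis=1)
    return row_sums / row_sums.sum()
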