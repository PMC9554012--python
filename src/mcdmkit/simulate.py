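"""Synthetic respondent panels with known ground truth.

The generator inverts the elicitation pipeline: from a target weight vector
it builds the unique consistent preference matrix that row-sum-normalizes
back to those weights (``p_ij = 0.5 + k (w_i - w_j) / 2``), takes its
adjacent chain, perturbs each chain value with additive Gaussian noise on
the fuzzy scale (clipped to [0, 1]), and emits Likert ratings as rounded,
clipped Gaussians around per-criterion true means.  With zero noise the
pipeline recovers the target weights exactly, which anchors every recovery
test; with noise, recovery error can be measured against the known truth.

The construction requires a bounded weight spread per group,
``k * (max w - min w) / 2 <= 0.5``, else some matrix entry leaves [0, 1]
(rescaling would distort the targets, so it is an error instead); use
:func:`compress_weights` to shrink a too-spread vector toward uniform.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .cfpr import FuzzyChain, PreferenceMatrix, WeightVector
from .datasets import load_hhnjs, load_reference_ipa, load_reference_weights
from .instrument import DIMENSION_GROUP, Instrument
from .panel import JudgmentRecord, RatingRecord, RespondentPanel, write_panel

__all__ = [
    "GeneratorConfig",
    "consistent_matrix_from_weights",
    "chain_from_weights",
    "compress_weights",
    "generate_panel",
    "write_truth",
    "hhnjs_generator_config",
    "simulate_to_dir",
]


def _spread(w: np.ndarray) -> float:
    return len(w) * (w.max() - w.min()) / 2.0


def consistent_matrix_from_weights(w: WeightVector) -> PreferenceMatrix:
    """The consistent preference matrix whose row-sum weights equal ``w``.

    ``p_ij = 0.5 + k (w_i - w_j) / 2``; reciprocity and additive
    transitivity hold by construction, and normalized row sums return ``w``
    exactly.  Requires spread ``k (max - min) / 2 <= 0.5`` so all entries
    stay in [0, 1].
    """
    arr = w.as_array()
    k = len(arr)
    sp = _spread(arr)
    if sp > 0.5:
        raise ValueError(
            f"group {w.group_id!r}: weight spread k*(max-min)/2 = {sp:.4f} > 0.5; "
            f"entries would leave [0, 1] — compress the weights toward uniform "
            f"(see compress_weights)"
        )
    p = 0.5 + k * (arr[:, None] - arr[None, :]) / 2.0
    return PreferenceMatrix(values=p, shift=0.0, rescaled=True)


def chain_from_weights(w: WeightVector) -> FuzzyChain:
    """Adjacent-pair chain of the consistent matrix for ``w``.

    Round-trips: feeding the chain back through completion and row-sum
    normalization recovers ``w`` (no rescale is triggered).  A length-1
    weight vector yields an empty chain.
    """
    if w.k == 1:
        return FuzzyChain(group_id=w.group_id, values=())
    m = consistent_matrix_from_weights(w)
    return FuzzyChain(
        group_id=w.group_id,
        values=tuple(m.values[i, i + 1] for i in range(w.k - 1)),
    )


def compress_weights(w: WeightVector, max_spread: float = 0.499) -> WeightVector:
    """Shrink a weight vector toward uniform until its spread is feasible.

    Returns ``u + lam * (w - u)`` with the largest ``lam <= 1`` such that
    ``k (max - min) / 2 <= max_spread``; the ranking (and ties) of the
    weights is preserved.  The default leaves a small margin below the hard
    0.5 bound so generated chains sit strictly inside [0, 1].
    """
    arr = w.as_array()
    sp = _spread(arr)
    if sp <= max_spread:
        return w
    lam = max_spread / sp
    u = 1.0 / len(arr)
    return WeightVector(group_id=w.group_id, weights=tuple(u + lam * (arr - u)))


@dataclasses.dataclass
class GeneratorConfig:
    """Ground truth and noise levels for one synthetic panel.

    ``true_weights`` maps every comparison group (the dimension chain plus
    one chain per dimension) to its target weight vector; ``true_performance``
    maps every criterion to a mean satisfaction on [1, 5].  ``judgment_noise``
    is the std-dev of additive Gaussian noise on the fuzzy chain values;
    ``rating_noise`` the std-dev of the latent Gaussian behind each Likert
    rating.
    """

    instrument: Instrument
    true_weights: dict[str, WeightVector]
    true_performance: dict[str, float]
    judgment_noise: float = 0.05
    rating_noise: float = 0.5
    n: int = 31
    seed: int = 0

    def validate(self) -> None:
        groups = self.instrument.groups()
        missing = set(groups) - set(self.true_weights)
        if missing:
            raise ValueError(f"true_weights missing groups: {sorted(missing)}")
        for gid, members in groups.items():
            wv = self.true_weights[gid]
            if wv.k != len(members):
                raise ValueError(
                    f"group {gid!r}: weight vector length {wv.k} != {len(members)} members"
                )
            sp = _spread(wv.as_array())
            if sp > 0.5:
                raise ValueError(
                    f"group {gid!r}: weight spread {sp:.4f} > 0.5 — "
                    f"compress the weights (compress_weights) before generating"
                )
        for cid in self.instrument.criterion_ids:
            mu = self.true_performance.get(cid)
            if mu is None:
                raise ValueError(f"true_performance missing criterion {cid!r}")
            if not (1.0 <= mu <= 5.0):
                raise ValueError(f"criterion {cid!r}: true mean {mu} outside [1, 5]")
        if self.judgment_noise < 0 or self.rating_noise < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.n < 1:
            raise ValueError("need at least one respondent")


def generate_panel(config: GeneratorConfig) -> RespondentPanel:
    """Draw a fully reproducible synthetic panel.

    Per respondent and group: the ideal chain from the group's true weights,
    plus independent ``N(0, judgment_noise^2)`` on each chain value, clipped
    to [0, 1].  Ratings are ``round(clip(N(mu_c, rating_noise^2), 1, 5))``.
    The respondent/group/criterion iteration order is fixed, so the same
    seed yields an identical panel.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    instrument = config.instrument
    groups = instrument.groups()
    ideal_chains = {gid: chain_from_weights(config.true_weights[gid]) for gid in groups}

    width = len(str(config.n))
    judgments: list[JudgmentRecord] = []
    ratings: list[RatingRecord] = []
    for r in range(1, config.n + 1):
        rid = f"R{r:0{width}d}"
        for gid, members in groups.items():
            ideal = np.asarray(ideal_chains[gid].values)
            if ideal.size == 0:
                continue
            noisy = ideal + rng.normal(0.0, config.judgment_noise, size=ideal.size) \
                if config.judgment_noise > 0 else ideal.copy()
            noisy = np.clip(noisy, 0.0, 1.0)
            for i, v in enumerate(noisy):
                judgments.append(
                    JudgmentRecord(
                        respondent_id=rid,
                        group_id=gid,
                        left_id=members[i],
                        right_id=members[i + 1],
                        value=float(v),
                        scale="fuzzy",
                    )
                )
        for cid in instrument.criterion_ids:
            mu = config.true_performance[cid]
            x = rng.normal(mu, config.rating_noise) if config.rating_noise > 0 else mu
            # half-up rounding keeps sigma=0 deterministic at .5 boundaries
            rating = int(np.floor(np.clip(x, 1.0, 5.0) + 0.5))
            ratings.append(RatingRecord(respondent_id=rid, criterion_id=cid,
                                        rating=min(rating, 5)))
    panel = RespondentPanel(instrument=instrument, judgments=judgments, ratings=ratings)
    panel.validate()
    return panel


def write_truth(config: GeneratorConfig, path: str | Path) -> None:
    """Dump the generator's ground truth as JSON for test harnesses."""
    payload = {
        "instrument": config.instrument.name,
        "n": config.n,
        "seed": config.seed,
        "judgment_noise": config.judgment_noise,
        "rating_noise": config.rating_noise,
        "true_weights": {g: list(w.weights) for g, w in config.true_weights.items()},
        "true_performance": dict(config.true_performance),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def hhnjs_generator_config(
    seed: int = 0,
    n: int = 31,
    judgment_noise: float = 0.05,
    rating_noise: float = 0.5,
) -> GeneratorConfig:
    """Default study-like configuration: the HHNJS instrument, 31 nurses.

    True group weights are the published reference local weights
    (renormalized to sum to 1 exactly); any group whose printed weights are
    too spread for the consistent-matrix construction is shrunk toward
    uniform just enough to become feasible, preserving its ranking.  True
    per-criterion means are the published reference performance scores.
    """
    instrument = load_hhnjs()
    ref_w = load_reference_weights()
    ref_ipa = load_reference_ipa()

    def normalized(gid: str, values) -> WeightVector:
        arr = np.asarray(values, dtype=float)
        return WeightVector(group_id=gid, weights=tuple(arr / arr.sum()))

    dim_block = ref_w.drop_duplicates("dimension")
    true_weights = {
        DIMENSION_GROUP: compress_weights(
            normalized(DIMENSION_GROUP, dim_block["dim_weight"].to_numpy())
        )
    }
    for d in instrument.dimensions:
        block = ref_w[ref_w["dimension"] == d.id]
        true_weights[d.id] = compress_weights(
            normalized(d.id, block["crit_weight"].to_numpy())
        )
    true_performance = dict(zip(ref_ipa["criterion"], ref_ipa["performance"].astype(float)))
    return GeneratorConfig(
        instrument=instrument,
        true_weights=true_weights,
        true_performance=true_performance,
        judgment_noise=judgment_noise,
        rating_noise=rating_noise,
        n=n,
        seed=seed,
    )


def simulate_to_dir(config: GeneratorConfig, out_dir: str | Path) -> RespondentPanel:
    """Generate a panel and write judgments.csv, ratings.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = generate_panel(config)
    write_panel(panel, out / "judgments.csv", out / "ratings.csv")
    write_truth(config, out / "truth.json")
    return panel
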