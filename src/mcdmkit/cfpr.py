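"""Consistent fuzzy preference relations (CFPR).

A fuzzy preference relation on ``k`` attributes is a ``k x k`` matrix of
pairwise preference intensities ``p_ij`` on ``[0, 1]`` with additive
reciprocity (``p_ij + p_ji = 1``).  A *consistent* relation additionally
satisfies additive transitivity::

    p_ij + p_jk - 0.5 = p_ik      for all i, j, k

which means the whole matrix is determined by the ``k - 1`` comparisons of
consecutive attributes ``(1,2), (2,3), ..., (k-1,k)``.  Eliciting only that
chain — instead of all ``k(k-1)/2`` pairs as in AHP — is what makes the
method practical for survey panels, and consistency holds by construction
rather than having to be checked after the fact.

Completion can push entries outside ``[0, 1]``; the standard transform
``f(x) = (x + a) / (1 + 2a)`` with ``a = max(0, max_ij p_ij - 1)`` maps them
back while preserving reciprocity, transitivity and the 0.5 diagonal.
Attribute weights are the normalized row sums of the rescaled matrix.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "FuzzyChain",
    "PreferenceMatrix",
    "WeightVector",
    "ratio_to_fuzzy",
    "complete_matrix",
    "rescale_matrix",
    "weights_from_matrix",
    "chain_weights",
]

#: absolute tolerance for reciprocity/transitivity/normalization invariants
ATOL = 1e-9


@dataclasses.dataclass(frozen=True)
class FuzzyChain:
    """The ``k - 1`` elicited adjacent preferences for one attribute group.

    ``values[i]`` is ``p_{i,i+1}`` on the fuzzy scale: 0.5 means indifference
    between attributes ``i`` and ``i + 1``, values above 0.5 favour ``i``.
    """

    group_id: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        bad = [v for v in vals if not (0.0 <= v <= 1.0)]
        if bad:
            raise ValueError(
                f"chain {self.group_id!r}: fuzzy preferences must lie in [0, 1], got {bad}"
            )

    @property
    def k(self) -> int:
        """Group size (number of attributes)."""
        return len(self.values) + 1


@dataclasses.dataclass
class PreferenceMatrix:
    """An additively reciprocal and transitive preference matrix.

    ``shift`` records the rescale constant ``a`` applied to map entries into
    ``[0, 1]`` (0.0 if none); ``rescaled`` is False for a freshly completed
    matrix whose entries may still lie outside the unit interval.
    """

    values: np.ndarray
    shift: float = 0.0
    rescaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"preference matrix must be square, got shape {self.values.shape}")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    def check(self, atol: float = ATOL) -> None:
        """Raise ``ValueError`` if reciprocity/transitivity/diagonal fail."""
        p = self.values
        if not np.allclose(np.diag(p), 0.5, atol=atol):
            raise ValueError("diagonal entries must equal 0.5")
        if not np.allclose(p + p.T, 1.0, atol=atol):
            raise ValueError("additive reciprocity p_ij + p_ji = 1 violated")
        # all-triple additive transitivity, vectorized over (i, j, k)
        lhs = p[:, :, None] + p[None, :, :] - 0.5  # lhs[i,j,k] = p_ij + p_jk - 0.5
        rhs = p[:, None, :]
        if not np.allclose(lhs, rhs, atol=atol):
            raise ValueError("additive transitivity p_ij + p_jk - 0.5 = p_ik violated")
        if self.rescaled and ((p < -atol).any() or (p > 1.0 + atol).any()):
            raise ValueError("rescaled matrix has entries outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class WeightVector:
    """Positive attribute weights for one group, summing to 1."""

    group_id: str
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        object.__setattr__(self, "weights", w)
        if len(w) == 0:
            raise ValueError(f"weight vector {self.group_id!r} is empty")
        if any(x <= 0.0 for x in w):
            raise ValueError(f"weight vector {self.group_id!r} has non-positive entries: {w}")
        if not math.isclose(sum(w), 1.0, abs_tol=ATOL):
            raise ValueError(f"weight vector {self.group_id!r} sums to {sum(w)}, expected 1")

    @property
    def k(self) -> int:
        return len(self.weights)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


def ratio_to_fuzzy(r: float) -> float:
    """Map a Saaty-scale ratio judgment ``r in [1/9, 9]`` to a fuzzy preference.

    Uses ``f(r) = (1 + log_9 r) / 2``: indifference (r = 1) maps to 0.5,
    extreme preference (r = 9) to 1.0, and reciprocal judgments map to
    complements, ``f(1/r) = 1 - f(r)``.
    """
    r = float(r)
    if not (1.0 / 9.0 <= r <= 9.0):
        raise ValueError(f"Saaty ratio must lie in [1/9, 9], got {r}")
    return 0.5 * (1.0 + math.log(r, 9))


def complete_matrix(chain: FuzzyChain) -> PreferenceMatrix:
    """Complete the full preference matrix from a chain of adjacent judgments.

    Upper-triangle entries follow from additive transitivity applied along
    the chain, ``p_{i,j} = sum of the chain values between i and j minus
    (j - i - 1)/2``; the lower triangle follows from reciprocity.  The result
    satisfies transitivity for every triple but may contain entries outside
    ``[0, 1]`` (``rescaled`` is False); apply :func:`rescale_matrix` next.
    """
    k = chain.k
    p = np.full((k, k), 0.5)
    cum = np.concatenate([[0.0], np.cumsum(chain.values)])
    for i in range(k):
        for j in range(i + 1, k):
            p[i, j] = cum[j] - cum[i] - (j - i - 1) / 2.0
            p[j, i] = 1.0 - p[i, j]
    return PreferenceMatrix(values=p, shift=0.0, rescaled=False)


def rescale_matrix(m: PreferenceMatrix) -> PreferenceMatrix:
    """Map a completed matrix into ``[0, 1]`` with ``f(x) = (x + a)/(1 + 2a)``.

    ``a = max(0, max_ij p_ij - 1)``, which by reciprocity also equals
    ``max(0, -min_ij p_ij)``.  The transform fixes 0.5, preserves reciprocity
    and additive transitivity, and preserves the ordering of entries.  If the
    matrix is already within ``[0, 1]`` it is returned unchanged (``a = 0``).
    """
    a = max(0.0, float(m.values.max()) - 1.0)
    if a == 0.0:
        return PreferenceMatrix(values=m.values.copy(), shift=0.0, rescaled=True)
    return PreferenceMatrix(values=(m.values + a) / (1.0 + 2.0 * a), shift=a, rescaled=True)


def weights_from_matrix(m: PreferenceMatrix, group_id: str | None = None) -> WeightVector:
    """Derive attribute weights as normalized row sums of a rescaled matrix.

    ``w_i = sum_j p_ij / sum_ij p_ij``; by reciprocity the denominator equals
    ``k^2 / 2``, so weights are positive and sum to 1, and their order follows
    the row-sum order.
    """
    row_sums = m.values.sum(axis=1)
    w = row_sums / row_sums.sum()
    gid = group_id if group_id is not None else ""
    return WeightVector(group_id=gid, weights=tuple(w))


def chain_weights(chain: FuzzyChain) -> WeightVector:
    """Weights for one group: complete, rescale, then normalize row sums.

    A single-attribute group (empty chain) gets weight ``(1.0,)``.
    """
    if chain.k == 1:
        return WeightVector(group_id=chain.group_id, weights=(1.0,))
    m = rescale_matrix(complete_matrix(chain))
    return weights_from_matrix(m, group_id=chain.group_id)
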