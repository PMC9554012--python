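# Methods

## The model

`mcdmkit` implements a hybrid multi-criteria decision-making (MCDM)
pipeline for evaluating Likert survey instruments that are organized as a
two-level hierarchy: *dimensions* (e.g. "salary and benefit") containing
*criteria* (the individual items). It answers two questions jointly: how
much does each item matter (*importance*), and how well is it currently
doing (*performance*)?

### Weight elicitation: consistent fuzzy preference relations

A full pairwise-comparison matrix over `k` attributes needs `k(k-1)/2`
judgments and is almost never consistent when humans fill it in. The CFPR
approach elicits only the `k-1` comparisons of consecutive attributes in a
fixed order and *derives* the rest from additive transitivity,

```
p_ij + p_jk - 0.5 = p_ik ,
```

so consistency holds by construction. Preferences live on `[0, 1]` with
additive reciprocity `p_ij + p_ji = 1`; ratio judgments on the 1/9–9 scale
are mapped in by `f(r) = (1 + log9 r)/2`. Completion can overflow the unit
interval; the affine transform `f(x) = (x + a)/(1 + 2a)` with
`a = max(0, max_ij p_ij - 1)` maps everything back while fixing 0.5 and
preserving reciprocity, transitivity and entry order. Weights are the
normalized row sums of the rescaled matrix (the denominator is `k²/2` by
reciprocity), which is deterministic, order-preserving, and the dominant
convention in applied CFPR work. Alternatives (eigenvector, geometric
mean) were deliberately not implemented: the row-sum rule is the only one
whose inverse is affine, which the synthetic generator exploits.

Per respondent there is one chain over the dimensions plus one chain per
dimension over its criteria. The chain order *is* the instrument order;
with noisy judgments a different elicitation order would complete to a
different matrix, so the order is part of the instrument definition, not a
free parameter. Rescaling is applied per matrix (per respondent per
group), never pooled.

### Aggregation, global weights, stability

Respondent weight vectors are combined by element-wise arithmetic mean per
group (each vector already sums to 1). Global criterion weights are the
product `w_dim × w_crit|dim`; they sum to 1 over the instrument. Ranks are
descending competition ranks ("1224") computed from full-precision values,
never from rounded printouts; ties keep instrument order in listings.

Panel stability is summarized by the confidence level

```
CL = (1/k) Σ_i |w_i^(n) - w_i^(n-1)| / w_i^(n) × 100% ,
```

comparing the aggregated weights from all `n` respondents against the
aggregate with one respondent removed, with a 5% pass threshold
(configurable). Two open choices were resolved as follows:

- **Which weights?** CL is computed on the composed *global* weights, built
  by the same group-mean-then-compose path the reported weight table uses.
  (Averaging per-respondent global vectors is not the same thing — the mean
  of products is not the product of means — and would diverge from the
  reported aggregate it claims to measure.)
- **Which respondent is dropped?** Default: the last in file order
  (`drop_last`). `loo_mean` and `loo_max` variants over all n single
  removals are available for robustness reporting.

### Importance-performance analysis

Performance of a criterion is its mean Likert rating over respondents;
importance is its global weight. Two thresholds split the plane into four
quadrants: I keep-up-the-good-work (high/high), II possible overkill
(low importance, high performance), III low priority (low/low), IV
concentrate here (high importance, low performance). Conventions:

- "high" means *≥ threshold*; a point exactly on both thresholds is in I.
- Threshold strategies: `grand_mean` (default), `median`, `scale_midpoint`
  (3.0 on the 1–5 performance axis, `1/m` on the importance axis for `m`
  criteria), or `fixed` values.
- Reverse-worded items are *not* recoded by default; performance is
  reported on the ratings as collected. A `reverse_code` flag applies
  `6 - x` to flagged items for analyses that want a uniform "higher is
  more satisfied" reading.

The bundled reference IPA table for the HHNJS admits only importance
thresholds in `(0.0295, 0.0312]` given its printed labels (a grand-mean
importance threshold of 1/30 ≈ 0.0333 would relabel three items), so the
golden tests and the acceptance script use the interval midpoint 0.0304 as
a fixed importance threshold together with the grand mean of the
performance column.

## The synthetic generator

The generator inverts the elicitation: for a target weight vector `w` the
unique consistent matrix with those row-sum weights is
`p_ij = 0.5 + k (w_i - w_j)/2`, and its superdiagonal is the ideal chain.
Per respondent, each chain value receives independent additive Gaussian
noise `N(0, σ_j²)` *on the fuzzy scale* (where the CFPR arithmetic
happens) and is clipped to `[0, 1]`; clipping rather than rescaling keeps
per-respondent matrices comparable and keeps the noiseless case an exact
round-trip. Ratings are `round(clip(N(μ_c, σ_r²), 1, 5))` with half-up
rounding; a two-parameter latent-Gaussian item model is deliberately
minimal — it supports recovery testing but does not emulate category
probabilities, respondent correlation, acquiescence bias or missingness,
so passing recovery tests says nothing about those features of real
panels.

The inverse construction requires the spread bound
`k (max w - min w)/2 ≤ 0.5`; otherwise some entry leaves `[0, 1]` and
rescaling it would distort the target. Infeasible targets are an error;
`compress_weights` shrinks a vector toward uniform (preserving its
ranking) to the default spread 0.499, leaving a small margin so generated
chains sit strictly inside the unit interval.

Default study-like conditions (`hhnjs_generator_config`): the bundled
HHNJS instrument (30 items, 8 dimensions), `n = 31` respondents, true
group weights set to the bundled reference local weights (renormalized to
sum to 1 exactly; the "relationship with peer" group exceeds the spread
bound at k = 4 and is compressed to feasibility, ranking preserved), true
rating means set to the reference performance column, `σ_j = 0.05` and
`σ_r = 0.5`. The noise defaults are chosen so that a 31-respondent panel
recovers every group weight vector with RMSE below 0.01 and its confidence
level lands well under the 5% threshold, i.e. a panel that behaves like a
coherent expert group rather than random responders.

## Numerical choices

- Invariant tolerance 1e-9 absolute (reciprocity, transitivity, weight
  normalization); completion arithmetic is exact up to float rounding, and
  the equation-solving oracle agrees with the closed-form completion to
  1e-12 for k ≤ 5.
- Reports print weights and performance with 4 decimals using decimal
  round-half-up (0.04925 → 0.0493), matching the usual print convention;
  full precision is kept internally.
- Degenerate inputs: a single-criterion dimension has an empty chain and
  weight 1; a single-respondent panel skips the confidence statistic
  (leave-one-out is undefined); n < 2 or an empty weight list is an error,
  never a silent default.
- CL denominators are aggregated weights, which are strictly positive by
  construction, so the statistic cannot divide by zero.

## Problem sizes in the test suite

Golden tests run on the 30-item reference tables directly. Simulation
tests use the study-like shape (n = 31) with fixed seeds; the noise-trend
check averages CL over 10 seeds at σ_j ∈ {0, 0.02, 0.05}, and the RMSE
bound was validated across a pilot sweep of seeds before freezing the one
used in the test. Property tests (hypothesis, derandomized) cover chains
up to k = 8 for structural invariants and k = 5 for oracle equality.

## Known limitations

- The reference panel's raw questionnaires are not public, so its printed
  confidence level (0.7%) cannot be recomputed; the statistic is instead
  verified by construction (0 for identical respondents, brute-force
  two-pass equality, monotone trend in noise).
- Only complete panels are supported; no imputation of missing judgments
  or ratings.
- No multiplicative-consistency (eigenvector/AHP) mode, no triangular
  fuzzy numbers, no incomplete-relation completion beyond the adjacent
  chain, no gap-score or diagonal IPA variants.
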