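# mcdmkit

Hybrid multi-criteria decision-making (MCDM) evaluation of Likert survey
instruments: **consistent fuzzy preference relations (CFPR)** for attribute
weighting, group aggregation with a leave-one-out stability statistic, and
**importance-performance analysis (IPA)** for quadrant-based improvement
priorities. It ships the 30-item / 8-dimension Home Healthcare Nurse Job
Satisfaction Scale (HHNJS) as a bundled instrument, together with a
synthetic respondent generator so every pipeline stage is testable with
known ground truth.

Intended users: health-services and service-quality researchers who run
small expert panels (tens of respondents) over a hierarchical
questionnaire and want item weights, ranks and an actionable
importance-vs-satisfaction map without eliciting full pairwise-comparison
matrices.

## The method in brief

For a group of `k` attributes, each respondent compares only consecutive
attributes — `k − 1` judgments `p_{i,i+1} ∈ [0,1]` (or 1/9–9 ratios,
mapped by `(1 + log₉ r)/2`). Additive transitivity
`p_ij + p_jk − 0.5 = p_ik` completes the full preference matrix, the
transform `f(x) = (x + a)/(1 + 2a)` rescales it into `[0,1]`, and weights
are normalized row sums. Dimension weights times within-dimension
criterion weights give global weights (summing to 1); competition ranks
order them. Stability is the confidence level

    CL = (1/k) Σᵢ |wᵢ⁽ⁿ⁾ − wᵢ⁽ⁿ⁻¹⁾| / wᵢ⁽ⁿ⁾ × 100%   (pass if < 5%)

comparing aggregated weights with and without one respondent. IPA then
pairs each criterion's global weight (importance) with its mean Likert
rating (performance) and splits the plane at two thresholds into
quadrants: **I** keep up the good work, **II** possible overkill, **III**
low priority, **IV** concentrate here.

## Worked example

Generate a synthetic 31-respondent HHNJS panel (true weights and rating
means follow the bundled reference tables, with judgment noise σ=0.05 and
rating noise σ=0.5), then run the pipeline on it:

```bash
mcdm simulate --n 31 --seed 7 --out demo
mcdm run --judgments demo/judgments.csv --ratings demo/ratings.csv --out demo_out
```

which prints

```
panel: n=31 respondents, 9 comparison groups (sizes 8, 5, 4, 3, 4, 2, 3, 4, 5)
confidence level: 0.2829% (< 5% threshold, drop_last)
IPA thresholds (grand_mean): importance 0.0333, performance 3.7667
quadrants: I=6, II=5, III=12, IV=7
wrote demo_out/weights.tsv and demo_out/ipa.tsv
```

Reading this: the 31 simulated respondents produce stable aggregate
weights (removing one respondent shifts the 30 global weights by 0.28% on
average, far under the 5% threshold), and with grand-mean thresholds the
30 items split into 6 strengths, 5 possible overinvestments, 12
low-priority items and 7 urgent-improvement items. The first rows of
`demo_out/weights.tsv`:

```
dimension  dim_weight  dim_rank  criterion  crit_weight  crit_rank  global_weight  global_rank
C1         0.1715      1         C11        0.1181       5          0.0203         24
C1         0.1715      1         C12        0.1445       4          0.0248         20
C1         0.1715      1         C13        0.1815       3          0.0311         16
```

"Relationship with patients" (C1) comes out as the most important
dimension (weight 0.1715, rank 1), close to the generator's true value
0.1731 — the elicitation noise perturbs but does not scramble the truth.
`demo_out/ipa.tsv` holds one `criterion, importance, performance,
quadrant` row per item, with the thresholds echoed in a footer line.

The same operations are available as a library (`mcdmkit.run_pipeline`,
`mcdmkit.generate_panel`, `mcdmkit.chain_weights`, ...); see
`docs/methods.md` for the model, conventions and limitations.

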