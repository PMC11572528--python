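# Methods

## The evaluation model

The package evaluates a cohort of questionnaire respondents on a weighted
three-level indicator hierarchy. Level-1 nodes are domains (professional
quality, psychological capital, emergency attitude in the packaged scale),
level-2 nodes are contents, and the 46 level-3 leaves are the Likert items
respondents actually answer. Every node carries a *local* weight — its share
within its sibling group, summing to 1 per group — and the product of local
weights along a leaf's root path is its *global* weight. Both are exposed:
clustering aggregation uses local weights level by level, the grey relational
scorer uses (normalised) global leaf weights.

### Delphi concordance and screening

Kendall's W is computed on within-expert average ranks with the standard tie
correction:

    W = 12 S / ( m² (n³ − n) − m Σ_j T_j ),   T_j = Σ (t³ − t) over tie groups

with S the sum of squared deviations of item rank sums from m(n+1)/2, m
experts and n items. Significance uses χ² = m(n−1)W on n−1 degrees of
freedom; for ≤ ~10 items an exact permutation p-value is available as a
cross-check. Ranks (not raw scores) are used because W is defined on
rankings. A round where every expert ties all items carries no ranking
information and is flagged degenerate rather than scored.

Indicator screening keeps an item iff its mean importance ≥ 3.5 and its
coefficient of variation ≤ 0.25 — a common Delphi practice default; both
thresholds are plain parameters, and the full per-item mean/sd/CV table is
returned so any screening decision can be audited.

### AHM weighting

Each expert compares a sibling group pairwise on the Saaty 1–9 scale,
producing a positive reciprocal matrix B. The attribute hierarchy model
converts B to attribute measures: with β > 0,

    b_ij = k > 1  →  u_ij = βk/(βk+1),  u_ji = 1/(βk+1)
    b_ij = 1, i≠j →  u_ij = u_ji = 1/2,           u_ii = 0

and weights are scaled row sums, w_i = 2/(n(n−1)) Σ_j u_ij. The pair-sum
identity u_ij + u_ji = 1 forces Σw = 1 exactly for any valid reciprocal
matrix, consistent or not — which is the practical appeal of AHM over AHP.
β defaults to 2 (the customary choice; β = 1 is exercised in tests).

The AHM transform is *nonlinear*: even a perfectly consistent matrix
b_ij = w_i/w_j does not return the generating w (two items with ratio 6
yield AHM weight 12/13, not 6/7). What the consistent limit guarantees — and
what the tests assert — is exact recovery by the AHP principal eigenvector
and recovery of the *ranking* by AHM. Recovery of planted weight *values*
is therefore judged at the panel level: 25 simulated experts with log-normal
judgment noise (sd 0.1) and Saaty quantisation, pooled by element-wise
geometric mean, reproduce the packaged scale's weights with mean absolute
error ≈ 0.026 (bound asserted: ≤ 0.05).

Expert pooling uses the geometric mean of matrix entries (the aggregation
that preserves reciprocity); arithmetic pooling of per-expert weight vectors
is available as an alternative. Aggregated entries fall off the integer
Saaty grid and are accepted with a warning, not rejected. AHP's consistency
ratio CI/RI (Saaty's published RI for n ≤ 15) is computed and reported as a
diagnostic but never used to reject matrices — AHM does not require
consistency.

### Grey whitening-weight clustering

Each of the four grades is a grey class with a whitening weight function
mapping a rating to a membership degree in [0, 1]. The published instrument
states only the functions' count and forms, never their turning points, so
the default scheme is a reconstruction chosen to tile the 1–5 axis:

| class     | form          | breakpoints |
|-----------|---------------|-------------|
| excellent | upper limit   | (4, 5)      |
| good      | triangular    | (3, 4, 5)   |
| medium    | triangular    | (2, 3, 4)   |
| poor      | lower limit   | (2, 3)      |

This tiling makes total membership identically 1 on [1, 5] (so no rating is
degenerate), maps rating 5 purely to "excellent" and ratings ≤ 2 purely to
"poor", and makes the composite score continuous and monotone in every
rating. A scheme of stacked upper-limit ramps (excellent (4,5), good (3,4),
medium (2,3)) was rejected because it leaves the integer rating 2 with zero
membership in every class and caps an all-top-rating cohort at composite 0.8
after renormalisation instead of the maximal grade value. All forms
(upper/lower limit, triangular, moderate) and breakpoints remain fully
configurable via YAML for other axis granularities.

Grade values default to (1.0, 0.8, 0.6, 0.4) — equally spaced, placing
composites in the 0.4–1.0 band conventional for such scales.

Scoring proceeds on two parallel paths sharing one recursion:

* **pooled** — per leaf, grey evaluation coefficients n_e = Σ_respondents
  f_e(x) normalise to the leaf's class-membership vector r = n/N; an internal
  node's vector is the local-weight mixture of its children's vectors,
  renormalised; composite = r · grade values. Because child vectors each sum
  to 1, the node composite is exactly the local-weight average of child
  composites, hence monotone in every rating;
* **per-respondent** — each respondent's own whitening memberships,
  normalised within each leaf, aggregated identically; the per-respondent
  composites give each node's median and interquartile range (the summary
  reported for skewed Likert-derived scores) and feed the group comparisons.

A leaf where every whitening value vanishes (possible under custom schemes)
is flagged degenerate and propagated as missing, never fatal.

### Grey relational grading

The reference series takes each leaf's maximal observed rating. For
respondent i and leaf k, Δ_ik = |x_ref,k − x_ik| and

    γ_ik = (Δmin + ρ Δmax) / (Δ_ik + ρ Δmax),

with Δmin/Δmax the global extrema over the table and distinguishing
coefficient ρ = 0.5 by default (configurable in (0, 1]). The relational
grade Γ_i averages γ_ik with global leaf weights normalised to sum exactly
to 1 — the printed local weights are rounded to 3 decimals, so raw global
weights sum to ≈ 0.9998, and normalising keeps the identity Γ(reference) = 1
exact. A constant table (Δmax = 0) defines every grade as 1.

### Group comparisons

Composite scores are compared across covariate groups with rank tests
(Mann–Whitney for two groups, Kruskal–Wallis beyond), average-rank tie
handling, and Bonferroni-adjusted pairwise rank-sum post-hocs (adjustment
method configurable through statsmodels' `multipletests`). Groups with
fewer than two members are excluded from pairwise testing and noted in the
result. Rank tests were chosen to match the median (IQR) reporting of the
scores; the tests run are recorded in the result object.

## Synthetic data

The generators stand in for unpublished survey and panel data; all are pure
functions of their seed.

* **Cohorts** — a graded-response latent-threshold model: respondent trait ~
  Normal(Σ group effects, trait_sd = 1), item intercepts ~ Normal(0, 0.3),
  residual noise sd 1; the latent sum is cut at (−1.2816, −0.5244, 0.2533,
  1.0364), placing roughly (10, 20, 30, 25, 15)% of mass across the five
  Likert categories at zero trait. Covariates (gender, years-of-work band,
  job nature, major, certificates, exercise habit, training, drill) are drawn
  from declared level fractions; group effects shift the latent mean of
  chosen levels. `n_invalid` records are blanked so complete-case filtering
  removes exactly that many — making the 417 → 347 questionnaire funnel and
  its 83.2 % recovery rate a testable computation rather than a constant.
* **Panels** — each expert judges b_ij as the Saaty value nearest (on the log
  scale) to (w_i/w_j)·exp(ε), ε ~ Normal(0, judgment_noise_sd), reciprocity
  by construction.
* **Delphi rounds** — expert latents mix a common item-quality vector
  (weight = concordance) with independent noise, binned to 1–5 by per-expert
  quintiles; concordance 1 gives identical rankings (W = 1), 0 gives
  independent ones.

What the generators do *not* emulate: real item-level multidimensionality
(one latent trait drives all 46 items), differential item functioning,
response styles (acquiescence, extreme responding beyond straight-lining),
or informative missingness. Passing recovery tests therefore demonstrate
that the pipeline's mathematics and inference behave correctly under a
clean, known data-generating process — not that any particular field
cohort's scores are reproduced.

## Numerical choices and problem sizes

* Sibling weight groups are validated to sum to 1 ± 5×10⁻³ (3-decimal
  printed weights make groups of 0.999/1.001 legitimate); global leaf
  weights to 1 ± 10⁻².
* Geometric-mean aggregation antisymmetrises the log matrix before
  exponentiating, so reciprocity is exact despite floating drift.
* AHP uses power iteration (positive matrices have a simple dominant
  eigenvalue) with a 10⁴-iteration cap and 10⁻¹² tolerance, cross-checked
  against a dense eigensolver in tests.
* Recovery percentages round half-up to one decimal (`Decimal`), matching
  survey-reporting convention.
* Monte-Carlo experiment sizes — 200 replicates for detection power of a
  0.5-latent-SD exercise-habit effect at n = 347, 400 replicates for the
  type-I error band, 25 experts for panel recovery — are the package's
  standard experiment sizes and complete in seconds to a couple of minutes
  on one CPU.

## Known limitations

* The default whitening breakpoints and grade values are reconstructions;
  absolute composite scores shift under other defensible schemes (orderings
  and group contrasts are far more stable).
* AHM weight values depend on β; only the ranking is β-invariant.
* The screening thresholds reproduce a realistic indicator funnel
  qualitatively; they are not estimates of any particular panel's criteria.
* Per-respondent and pooled composites answer different questions (the
  pooled vector is not the mean of per-respondent vectors after
  renormalisation); both are reported.
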