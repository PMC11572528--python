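# resilgrey

Evaluation modelling for **emergency-resilience questionnaire scales** — the
kind of instrument used to assess how well grassroots (community) medical
workers can resist, absorb and recover from public health emergencies.

The package implements the full methodology chain such scales are built and
applied with:

1. **Delphi panel statistics** — Kendall's coefficient of concordance *W*
   (tie-corrected) per consultation round, and mean/CV indicator screening;
2. **AHM weighting** — indicator weights from Saaty 1–9 pairwise comparison
   matrices via the *attribute hierarchy model*, which converts the
   comparison matrix into an attribute-measure matrix (u_ij + u_ji = 1) and
   takes scaled row sums — no eigenvector, no consistency requirement.
   Classical AHP (principal eigenvector, consistency ratio) is included as a
   diagnostic cross-check, and expert panels are pooled by the element-wise
   geometric mean;
3. **Grey scoring** — each grade ("excellent", "good", "medium", "poor") is a
   grey class with a piecewise-linear whitening weight function over the
   Likert axis; whitening values pool into grey evaluation coefficients,
   normalise into class-membership vectors, aggregate up the weighted
   indicator tree and collapse into composite scores via grade values. A grey
   relational scorer (γ = (Δmin + ρΔmax)/(Δ + ρΔmax)) grades each respondent
   against the ideal reference series;
4. **Group comparisons** — rank-sum / Kruskal–Wallis tests of composite
   scores across covariates (exercise habit, training, years of work, …) with
   Bonferroni-adjusted pairwise post-hocs;
5. **Synthetic data with planted truth** — Likert cohorts from a latent-trait
   threshold model with plantable group effects and invalid records, noisy
   Saaty panels from planted weight vectors, and Delphi rounds with a
   concordance dial.

A transcription of a published 3-level emergency-resilience scale (3 domains,
13 contents, 46 items, with AHM weights — e.g. psychological capital at
0.614) ships as the packaged default scale in YAML and CSV dialects.

## Worked example

```python
from resilgrey import (CohortSpec, GreyEvaluationModel, ValidityRule,
                       filter_valid, load_packaged_scale, recovery_rate,
                       simulate_cohort)

tree = load_packaged_scale()
cohort = simulate_cohort(
    CohortSpec(n_respondents=417, n_invalid=70, seed=11,
               group_effects={"exercise_habit": {"stable": 0.5}}),
    tree,
)
filt = filter_valid(cohort, ValidityRule())
print("recovery:", recovery_rate(417, filt.valid.n_respondents), "%")

results = GreyEvaluationModel(filt.valid, tree).fit()
print(results.summary(levels=(0, 1)))

cmp = results.compare_by("exercise_habit")
print(f"{cmp.test}: H = {cmp.statistic:.2f}, p = {cmp.p_value:.4f}")
```

prints

```
recovery: 83.2 %
Grey whitening-weight evaluation
========================================================================
respondents: 347    leaves: 46    classes: excellent, good, medium, poor
grade values: excellent=1, good=0.8, medium=0.6, poor=0.4
------------------------------------------------------------------------
node       level  composite   median     IQR   r_exce  r_good  r_medi  r_poor
overall        0     0.6816   0.6633  0.2723   0.2670  0.1998  0.2076  0.3257
x1             1     0.6816   0.6700  0.2882   0.2660  0.2038  0.2021  0.3281
x2             1     0.6812   0.6700  0.2502   0.2666  0.1977  0.2108  0.3249
x3             1     0.6889   0.6784  0.2720   0.2808  0.1985  0.2052  0.3155
------------------------------------------------------------------------
mean grey relational grade (rho=0.5): 0.6227
kruskal-wallis: H = 22.45, p = 0.0000
```

417 questionnaires were simulated with 70 planted-invalid records; complete-
case filtering recovers 347 (83.2 %). Each node row shows the pooled
class-membership vector (r\_\*), its grade-value composite on the 0.4–1.0
band, and the median/IQR of the per-respondent composite scores. The planted
exercise-habit effect (+0.5 latent SD for the "stable" group) is picked up by
the Kruskal–Wallis omnibus test.

The same pipeline is scriptable from the shell:

```bash
resil-grey simulate cohort --seed 11 --out cohort.csv
resil-grey evaluate --responses cohort.csv --out scores.csv
resil-grey run --config config.yaml --out outdir/   # full pipeline + manifest
```

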