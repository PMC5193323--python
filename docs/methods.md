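# Methods

## Tissue-specificity index

τ = Σᵢ (1 − xᵢ/max xᵢ)/(n − 1) over the n retained tissues, on log₂
expression. The log transform floors linear values below 1 at 1
(`log2(max(v, 1))`), so expression below 1 RPKM maps to 0 and is treated
as absence. The floor, rather than `log2(x + 1)`, keeps τ's numerator
exact for one-hot profiles (τ = 1 whenever a single tissue is expressed)
and makes "undefined τ" (no tissue ≥ 1 RPKM) an explicit state instead of
a numerical accident; the transform is confined to one function, so a
different convention is a one-line change. τ is undefined when the
maximum transformed value is 0; undefined genes are kept in tables with
`defined = False` and silently dropped (with logged counts) by the
correlation stages.

Specificity calls use τ ≥ 0.8 by default (threshold configurable, and the
pipeline sweeps {0.3, 0.8} for the same-tissue analysis). The main tissue
is the highest-expressed tissue **on linear scale**; ties break by tissue
column order, deterministically, with a logged tie count. The testis
override, when enabled, additionally calls every defined gene whose main
tissue is testis "testis-specific" regardless of τ, flagged separately
(`testis_forced`) so the τ-threshold invariant remains auditable.

## Analysis units

* **Ortholog pairs** — one per one-to-one ortholog row between the focal
  species and each comparison species, dated at the speciation node. A
  gene appearing in two one-to-one rows for the same species pair is
  treated as a data error, not silently resolved.
* **Paralog pairs** — per gene, the most recently diverged within-species
  paralog (minimum duplication-node age), with multifurcation ties broken
  by the partner's maximal expression and then lexicographic id. The pair
  set is deduplicated and, within an age class, each gene appears in at
  most one pair (conflicts resolved toward the pair with the higher
  maximal expression). Across age classes reuse is allowed and logged.
  Each pair is oriented so `gene_ref` is the copy with the higher maximal
  linear expression (ties: lexicographically smaller id). The linear peak
  is used because maximal expression is most naturally read on the raw
  scale.
* **Outgroup triplets** — a paralog pair plus a single unduplicated
  outgroup gene co-orthologous (one-to-two) to both members, with the
  outgroup speciation at least as old as the duplication; when several
  species qualify, the youngest qualifying split is used.

Ages come from a node-label → million-years calibration table
(TimeTree-style); a label missing from the calibration raises a lookup
error naming the label at use time.

## Statistics

Correlation points require ≥ 3 pairs with defined τ on both sides; points
below that are dropped with a warning. Zero variance on either side is an
error rather than NaN propagation.

**Decay shape.** `r ~ age` and `r ~ log10(age)` have the same parameter
count, so they are compared two ways: by residual sum of squares, and
(default criterion) by the added-variable F-test of `log10(age)` entering
a model that already contains `age`. The default is exact under the
linear null — the preference rate for the log model equals the nominal α
(verified at 5% by simulation in the test suite) — whereas a raw RSS
preference would flag the log model about half the time under the null.
With fewer than three distinct ages the two predictors are collinear and
the comparison is reported as undefined.

**Group contrasts.** Ortholog-vs-paralog and condition effects (e.g. τ
without testis vs with all tissues) use the nested F-test of
`r ~ age` against `r ~ age + group`. Points are unweighted: the varying
pair counts behind each point are recorded but not used as regression
weights, matching the treatment of each age class as one observation.

**Multiple testing.** Storey q-values with the fixed-λ estimate
π₀ = #{p > 0.5}/(m/2), capped at 1, times the Benjamini–Hochberg adjusted
p-values. The fixed λ keeps the battery deterministic; with very small
batteries π₀ can degenerate to 0, which is documented in the function and
left to the caller. The battery is whatever set of model comparisons the
run actually performed, recorded test-by-test in the report.

**Same-tissue analysis.** Pairs where both members are specific are split
by whether their main tissues agree after translation to canonical labels
through the tissue map; unmapped tissues exclude the pair and are
counted, so `n_same + n_different + n_excluded` always equals the number
of both-specific pairs. Tissue matching is needed only here — τ itself
never requires matched tissue panels.

## Synthetic data generator

The generator provides ground-truth data with the study's statistical
structure; it is a test harness, not a mechanistic claim about expression
evolution.

* **Ancestors.** Linear profile = peak level × Dirichlet share vector,
  normalised so the peak tissue carries the drawn level.
  log₂ peak ~ N(6, 2) (median ≈ 64 RPKM, wide range). Shares come from a
  two-component mixture: 40% "specific" (concentration 0.1 → near one-hot
  profiles, τ ≈ 1) and 60% "broad" (concentration 30 → near-uniform,
  τ ≈ 0); drift fills in intermediate values at the tips. Among specific
  ancestors, 40% have their peak placed in testis, reflecting testis'
  outsized share of tissue-specific genes; this is what makes the
  "τ without testis" control bite.
* **Drift.** Brownian motion in log₂ space with σₑ = 0.15 per √My,
  applied along a caterpillar species tree (focal lineage with branches
  at 6, 25, 90, 160, 300 and 361 My, mirroring a primate-to-frog
  comparison panel). Tip values are floored at 0. All tips share one
  lineage history, so every pairwise correlation is tree-consistent. The
  resulting ortholog τ correlations decay smoothly (≈ 0.99 at 6 My to
  ≈ 0.78 at 361 My at the default σₑ).
* **Duplication.** At a scenario age, the focal-lineage state splits into
  two copies. Dosage sharing gives the major copy 70% of the linear
  level; the minor copy loses fraction λ = 0.8 of its expression outside
  its peak tissue (immediate asymmetric loss), or — in the ohnolog
  scenario, with probability 0.5 — re-specifies by swapping its peak into
  another tissue. Both copies then drift for the scenario age while
  non-peak tissues rise deterministically at 0.002 log₂/My
  (broadening). The unequal dosage split (70/30) is what lets the
  expression-based orientation recover the major copy; with an even split
  the roles would be unidentifiable from the tips.
* **Outgroups.** Each duplication class is linked to the closest species
  whose split is strictly older than the duplication (e.g. 90-My
  duplicates → the 160-My species), as an unduplicated co-ortholog. The
  oldest (500 My) class has no qualifying outgroup, matching the poor
  outgroup situation for vertebrate whole-genome duplicates.

Defaults: 3000 single-copy genes, 250 families per duplication class at
25, 90, 160, 300 My (small-scale) and 500 My (ohnolog-like,
re-specifying). Tests and the acceptance script scale `n_genes` and the
scenario list down where a property needs many seeds; the properties
checked are size-robust (direction and significance, not magnitudes).

What the generator does **not** emulate: count noise (values are
abundances, not reads), correlated drift between tissues, gene loss,
varying tissue panels between species, rate variation across genes, and
mean reversion (no OU term). Passing tests therefore demonstrate that the
pipeline recovers the encoded patterns under a clean Brownian model, not
that real data will show them.

## Numerical and degenerate-input choices

* Missing expression values are an error (no imputation rule exists worth
  silently applying).
* Correlation points need ≥ 3 pairs; decay fits need ≥ 4 points with ≥ 2
  distinct ages; the model comparison needs ≥ 3 distinct ages.
* All report tables are written with `%.6g` floats and stable sort
  orders, making reruns byte-identical; all randomness in a run descends
  from a single seed.
* An empty paralog table degrades gracefully: the report is produced with
  paralog sections absent and flagged in the summary.

## Known limitations

* The added-variable decay comparison tests whether the log shape adds
  explanatory power on top of the linear one; it is not a symmetric
  non-nested model test (e.g. Vuong), which the small point counts here
  would not support.
* π₀ estimation at fixed λ is noisy for batteries under ~30 tests.
* No phylogenetic correction of the regression points: age classes are
  treated as independent observations.
* Transcript-level (alternative-splicing) specificity is out of scope;
  the unit of analysis is the gene.
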