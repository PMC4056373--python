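# Methods

## Measurement model and scoring

A colony size is modeled as `z = base_size · p · f_q · f_a · exp(ε')`,
where `p` captures plate-to-plate growth differences and `f_q`, `f_a` are
single-mutant fitnesses. The preprocessing chain estimates and removes the
systematic factors:

1. **Colony filter.** Missing measurements and sizes outside
   `[min_size, max_size]` are dropped (defaults: 1 raw unit and 10× the
   median of per-plate median sizes). This simple bounds filter stands in
   for full spatial-artifact correction; position-dependent gradients
   within a plate are not modeled or corrected.
2. **Plate-mode normalization.** Each plate is divided by the mode of a
   Gaussian kernel density estimate over its sizes (Silverman bandwidth,
   argmax on a 512-point grid spanning the plate's range; a zero-spread
   plate returns its common value directly). The mode is used instead of
   the mean because dead colonies and strong interactions bias the mean
   downwards while leaving the bulk mode intact. Plates need ≥ 10
   measurements; the common `target_scale` defaults to the median of plate
   modes so typical colonies keep their raw magnitude. Because each plate
   carries a single query, this division absorbs `p · f_q` jointly and no
   separate query-fitness estimate is needed.
3. **Residuals.** The array fitness is the median normalized size of each
   array gene across all plates (conditions pooled by default; a
   per-condition option exists), and is subtracted to give the interaction
   residual ε. Arrays observed fewer than `min_obs = 6` times are dropped.
   Residuals are additive on the normalized scale even though the
   generative model is multiplicative; for the noise magnitudes of
   interest (log-scale sd ≲ 0.2) the approximation error is second order.

**Differentials and the dS score.** For each pipeline replicate,
`δ = ε_treatment − ε_reference`, matched on (query, array, replicate);
noise shared by the two conditions within a replicate cancels exactly in
this subtraction. Two scores are implemented:

- `one_sample`: the paired t-statistic `δ̄ / (s_δ/√n)`.
- `pooled` (default): the pooled-variance two-sample t of the pair's
  deltas against all deltas on the same array gene, with the focal pair's
  own deltas excluded from the comparison group to avoid self-dilution.

The pooled form is the default because it additionally absorbs array-level
condition responses (a single-mutant fitness change under treatment shifts
every query's delta on that array equally and is not a differential
*interaction*); the one-sample form is the literal paired t-statistic and
is exposed via `mode=`. The two agree in rank order (Spearman > 0.95 on
simulated screens). Neither applies a variance floor, moderation or prior;
the sample variance is used as-is. The static S-style comparator
(`s_score`) retains the conventional minimum bound — the pair's sd is
floored at the dataset-wide median per-pair sd — applied to
single-condition residuals. Pairs need ≥ 2 deltas (a warning is issued
below 4); zero-spread pairs with nonzero mean are flagged degenerate and
left unscored rather than given an infinite statistic.

## Empirical null and FDR

The null score sample is built by pairing replicates *within* each
condition (seeded random perfect matching; an odd replicate is dropped
with a warning), differencing each matched pair as if it were a
cross-condition pair, pooling the pseudo-differentials of both conditions
per gene pair, and scoring through the identical dS path. With six
pipeline replicates per condition this yields six pooled null deltas per
pair, matching the six cross-condition deltas of the observed score, and
for iid normal residuals the one-sample null scores follow Student t(5)
exactly.

The FDR at a cutoff is `min(1, P_null(beyond) / P_obs(beyond))`, computed
per signed tail (`≥ cutoff` positive, `≤ cutoff` negative). No
monotonization is applied by default (an isotonic step-down flag exists).
`fdr_cutoff` returns the least extreme observed score whose estimated FDR
meets a target. With a null of a few thousand scores the extreme tail is
resolved in steps of `1/n_null`, so FDR-controlled cutoffs are noticeably
seed-dependent in the far tail; realized error control remains within the
estimator's resolution (about ±0.05 at the 0.05 operating point on
2,000-pair screens), but users wanting stable cutoffs should score larger
screens or pool nulls across screens.

## Similarity, associations, bootstrap

Profile similarity is the Pearson correlation of two genes' score vectors
over mutually observed partners, requiring `min_overlap = 10` shared
entries (zero-variance overlaps are left missing). The differential
association filter selects gene pairs with differential similarity
> 0.35 whose static similarity stays < 0.15 in **every** supplied static
matrix (the conservative max rule; an `any` rule is available). The
paired bootstrap compares two correlation coefficients over the same gene
pairs by resampling pair indices jointly (default 10,000 iterations);
ties contribute 1/2 to the one-sided count.

## Diagnostics

The **variance decomposition** computes, per double mutant, the two
per-condition residual variances, their sum (the differential variance
expected if conditions were independent) and the observed variance of the
deltas. With a fraction ρ of the residual variance shared between
conditions, the observed differential variance is `2(1−ρ)σ²` rather than
`2σ²`; the dataset medians quantify this deflation.

**Split-replicate reproducibility** scores two disjoint replicate subsets
independently and reports the Pearson correlation of the two score vectors
within the top fraction of pairs, ranked by the mean of |score| across the
two splits (ranking by either split alone would bias the selection toward
that split). Fisher-z 95% intervals are attached; rows with < 3 pairs are
skipped. Overlapping splits are allowed only as a consistency check and
warn.

**Enrichment** ranks scored pairs by |score| (signs treated equally;
signed ranking optional), with ties broken lexicographically for
reproducibility. Square matrices are collapsed to unordered pairs
(diagonal dropped, the larger-magnitude of the two symmetric entries
kept). Standard pairs never scored are excluded from the recall
denominator, so recall is over the evaluable universe.

## The simulator

`simulate_experiment` emulates the paired pipeline: one plate per (query,
replicate, condition), the treated and untreated plate of a replicate
sharing their per-(query, array, replicate) noise draw `u` (log-scale sd
`sigma_shared`, default 0.15) on top of condition-specific noise `v`
(`sigma_cond`, default 0.05). Plate effects are LogNormal(0,
`plate_effect_sd` = 0.1); fitnesses are Normal(1, `fitness_sd` = 0.1)
truncated at 0.05, drawn once per gene and shared across conditions —
per-condition fitness responses can be switched on via
`condition_fitness_sd` but are off by default, since they are single-gene
condition effects rather than interactions. Static and differential
interaction effects (disjoint pair sets, Rademacher signs, magnitude
`effect_size` on the log/residual scale, the differential one active only
in the treatment) enter the exponent alongside the noise. Default plate
geometry is 16×24 with arrays laid out row-major; `base_size = 300` raw
units approximates typical colony quantification scales. Everything is
deterministic given `seed`.

Consequences used by the tests: differential variance ≈ `2·sigma_cond²`
regardless of `sigma_shared`, static residual variance ≈
`sigma_shared² + sigma_cond²` — both in units of
`(target_scale · f_a)²`, so quantitative variance checks normalize by
`target_scale` and pin `fitness_sd = 0`. Standard study conditions used
throughout the test suite: 20 queries × 100 arrays × 6 replicates × 2
conditions (2,000 gene pairs, 24,000 colonies), which keeps any single
simulation under a few seconds.

What the simulator does **not** emulate: spatial gradients across the agar
surface, pinning-order and neighborhood competition effects, batch drift
across plates of the same replicate, non-normal heavy-tailed measurement
error, and linkage between query and array loci. Passing recovery and
calibration tests therefore demonstrate correctness of the statistical
machinery under the stated noise model, not robustness to every artifact
of real plates — the bounds filter plus mode normalization address only
the artifact classes they were designed for.

## Numerical and edge-case choices

- KDE mode grid: 512 points over [min, max]; resolution ~0.2% of the data
  range, well below plate-to-plate variability.
- Degenerate samples (zero spread) short-circuit before KDE or t
  computation; scores of flagged-degenerate pairs serialize as `NA`.
- Float I/O is exact round-trip: colony sizes are parsed with Python float
  conversion and matrices are written at 17 significant digits and read
  with round-trip precision.
- FDR ratios above 1 are clamped with a log message; empty observed tails
  yield missing values with a warning rather than zero.
- Replicate matching, bootstrap resampling and random-query sampling all
  draw from `numpy.random.default_rng` seeded explicitly; no global state.

## Known limitations

- The empirical-null resolution bounds how finely FDR can be controlled
  (see above); there is no parametric fallback by design.
- The one-sample dS is sensitive to array-level condition responses if
  array fitnesses are estimated pooled across conditions; the pooled mode
  or per-condition fitness estimation mitigates this.
- Spatial-artifact correction is out of scope; data with strong positional
  effects should be pre-corrected upstream.
- Precision-recall against user-supplied standards inherits whatever
  ascertainment bias the standard carries; the package only restricts to
  the evaluable universe, it cannot correct the standard itself.
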