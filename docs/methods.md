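# Methods

This note documents the statistical machinery in `uromics`: the models,
their assumptions, the defaults and why, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Data model

An intensity matrix is features × samples, nonnegative, with 0 meaning
"below detection".  Missing cells in input files are read as 0 (with a
logged count), never as NaN: every filtering rule downstream is a
presence/absence rule, and a value that was not detected is treated as
absent, not unknown.  Blanks (ambient-air controls) are ordinary columns
distinguished only by their annotation role; they have sex `NA`.
Technical replicates are not merged by the package — each column is one
sample, and merging repeated collections per individual is the caller's
responsibility.

## Blank-aware filtering

The funnel runs in a fixed order; stage counts are monotone by
construction and every dropped feature carries a drop reason.

1. **Prevalence.**  Keep a feature iff at least `min_count` (default 3)
   specimens of some group × sex cell detected it.  Counting per cell, not
   per whole dataset, protects group-specific molecules produced by only
   one subpopulation.  Blanks never count.
2. **Blank-only removal.**  Drop features with signal in ≥ 1 blank and in
   0 specimens.  "Only in blanks" is strict: one specimen detection is
   enough to survive to the next stage.
3. **Mixture filter.**  For each remaining feature,
   `x = log2((mean_specimens + ε)/(mean_blanks + ε))` with a
   pseudo-intensity ε defaulting to half the smallest nonzero value in the
   matrix.  Ambient contaminants cluster near x = 0 (equal abundance in
   specimens and blanks); biological molecules sit several log2 units
   higher, giving a bimodal histogram.  A two-component univariate normal
   mixture is fitted by EM and a feature is kept iff the posterior
   probability of the higher-mean ("biological") component is
   ≥ `posterior_threshold` (default 0.95, i.e. ≤ 5 % posterior mass on the
   blank-overlap side).

The fold-difference and identity-index cutoffs implied by the posterior
rule are *reported*, not imposed: the x value at which the posterior
crosses the threshold depends on the fitted components, so the equivalent
FD (or LI) cutoff is a property of each dataset.  LI and FD are computed
on raw means; no algebraic correspondence between an FD cutoff and an LI
cutoff is forced, because the two are consistent only under specific
scale conventions.

**EM numerics.**  Initialization is deterministic: the sample is split at
its median and each half supplies one component's starting moments.
Convergence requires a log-likelihood improvement < 1e-8 (up to 1000
iterations); sigmas are floored at 1e-6; a degenerate sample (all values
equal) returns a non-converged fit rather than crashing.  The monotone
log-likelihood path is stored and asserted in tests.  A deterministic
start was chosen over the common random-restart strategy so the whole
pipeline is reproducible from a single seed; with two well-separated
components the EM surface has no competitive local optima.

Protein matrices pass only through stage 1 — there are no procedural
blanks for LC-MS/MS proteomics in this design.

## Quantile normalization

The reference distribution is the row-wise mean of the column-sorted
matrix; each column's values are replaced by the reference values at
their ranks, ties receiving the mean of the reference values at the tied
ranks ("average" dialect).  Zeros participate like any other value — they
are real below-detection observations, and masking them would shift every
column's distribution by its own detection rate.  The transform is
idempotent and rank-preserving within columns; note that tie averaging
means columns with different tie structures can differ microscopically in
their value multisets — exact multiset equality holds for tie-free data.

## Power-law global error model

With ≤ ~10 replicates per condition, per-feature variances are too noisy
to test on.  The global error model assumes a power-law mean-variance
relation across features within one condition:

    SD(μ) = e^b · μ^m        (m ≈ 0.5–1 in practice)

fitted by OLS of ln SD on ln mean over the features fully detected in the
most-replicated group × sex cell (ties broken lexicographically;
overridable).  Zeros are excluded from the fit and from condition means:
the error model describes detected intensities, and pseudo-counting
below-detection values would bend the low-mean end of the fit.

Differential abundance between conditions A and B is scored by

    STN = (μ_B − μ_A) / (SD(μ_A) + SD(μ_B))

and referenced against an empirical null built by repeatedly partitioning
the replicates of one condition into two pseudo-groups and pooling the
resulting STN values across features and iterations (default 500
iterations).  Because a half-split of k replicates estimates mean-noise at
sizes (⌊k/2⌋, ⌈k/2⌉) while the tested contrast has its own replicate
counts (n_A, n_B), the pooled null is rescaled by
`sqrt((1/n_A + 1/n_B)/(1/⌊k/2⌋ + 1/⌈k/2⌉))` — the mean-difference
standard deviation scales this way under the shared error model.  Without
the rescaling, p-values for contrasts larger than the half-split are
conservative; with it, null-feature p-values are approximately uniform
(KS < 0.08 in the test suite).  Empirical p-values use the add-one rule
`p = (r + 1)/(n + 1)`, so p is never exactly 0.

Fold differences follow the signed female-over-male convention: ratios
below 1 are reported as −1/FD, so "|FD| > 2" reads symmetrically on both
sides.  A molecule is *significant* iff `p < alpha` (default 0.05, raw —
no multiplicity correction by default, matching the headline rule;
Benjamini-Hochberg is available via `adjust="bh"`) and `|FD| > 2`.
PLGEM runs on linear intensities, its native scale.

## Sex-bias asymmetry

Significant calls from a volatile table and a protein table (same group
contrast) are tallied into a 2×2 table (rows male-/female-biased, columns
volatiles/proteins) and tested with Fisher's exact test, two-sided by the
"probability mass ≤ observed" rule.  A zero margin leaves nothing to
test and returns p = 1, flagged.  The odds ratio is the cross-product
with a 0.5 continuity correction when any cell is zero.  The table
contrasts bias direction against layer; an alternative design would
contrast biased counts against all tested features per layer, which
answers a different question (enrichment of bias per layer rather than
asymmetry of direction across layers) and is not implemented.

Cross-group comparisons use exclusive (UpSet) intersection semantics:
every feature is counted in exactly one subset — the set of groups whose
biased sets contain it — so counts partition the union.

## Latent-variable integration

PLS-DA regresses the standardized feature block on a centered one-hot
class indicator via NIPALS power iterations; optional sparsity
soft-thresholds each weight vector so exactly `keep` features remain
nonzero per component.  Deflation is by X-scores, making score vectors
orthogonal.  Component signs are arbitrary in PLS; components are
oriented so the lexicographically last class has the higher mean score.
Columns are centered and unit-scaled exactly once, internally — feeding
pre-standardized data changes nothing.  In-sample discriminant scores
overfit badly at omics dimensionality (hundreds of features, tens of
samples), so chance-level behaviour under label permutation is only
visible in the cross-validated AUC helper, which projects held-out
samples through the training fit.

Two-block PLS is the canonical variant: alternating least squares on the
cross-covariance of two standardized blocks, deflating each block by its
own scores.  Component-1 weights equal the leading singular vectors of
the centered cross-covariance matrix (asserted to 1e-6 against an SVD in
tests).  The per-component Pearson correlation between paired block
scores quantifies proteome-metabolome correspondence; it is an analogue
of, not a replica of, the correlation reported by multi-block
discriminant frameworks, whose component definitions differ across
software dialects.

The correlation network computes Pearson r between every cross-block
feature pair on log2 intensities and keeps edges above `r_threshold`
(default 0.62; 0.6 is the conventional preset for restricted
carrier-protein subsets).  Pearson rather than Spearman because the
thresholds of interest are defined on abundance profiles, and the log2
transform already tames the heavy tails.  Constant features are excluded
(r undefined).  AUC is the rank statistic U/(n₁n₂) with ties counted
half — invariant under monotone score transforms.

## Random-forest importance

Importance is the mean over trees of the drop in out-of-bag accuracy when
one feature's values are permuted among that tree's OOB samples —
permutation importance, not impurity importance, which is biased toward
high-variance features.  The bootstrap, OOB bookkeeping and permutation
pass are implemented directly over sklearn decision trees because
sklearn's own `permutation_importance` operates on a supplied evaluation
set, not on the per-tree OOB samples.  Features unused by a tree's splits
cannot change its predictions, so they contribute exactly 0 for that tree
and are skipped — a pure optimization.  All tree and permutation
randomness derives from one seed; identical seed + input gives an
identical table.  Default 1000 trees for rank stability.

The absolute scale of mean-decrease importance depends on class balance,
redundancy among informative features and the ensemble dialect; the 0.1
"top molecule" threshold is a dataset-specific convention, which is why
`top_features` exposes it as a parameter and ranks are preferred for
cross-group comparisons.  Rank similarity between importance tables uses
Spearman's rho (average-rank ties), with an exact permutation p-value for
n ≤ 10 shared features and the t-approximation above that.

## Synthetic-data generator

The generator emulates the study design: 3 groups × 2 sexes ×
`n_per_cell` specimens (default 9, total 54, near the real 56) plus 6 air
blanks; 1200 volatiles and 500 proteins.  Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| `blank_fraction` | 0.4 | ~40 % of untargeted volatile features are ambient |
| `mix_params` | (0.4, 0, 1, 6, 1) | blank-overlap at x≈0, biological ~6 log2 units above, unit SDs |
| `effect_fd` | 4 | comfortably above the |FD| > 2 call threshold |
| sex-biased counts | 60/15 volatiles M/F, 10/45 proteins M/F | male-volatile / female-protein asymmetry |
| `plgem_slope`, `plgem_intercept` | 0.75, ln 3 | ≈20 % CV at the median abundance, slope in the empirical LFQ range |
| `replicate_sigma` | 0.5 | ~40 % CV for volatile peak areas |
| `n_pairs`, `pair_r` | 10, 0.8 | strong carrier-ligand coupling |
| `dropout_rate`, `dropout_quantile` | 0.3, 0.2 | below-detection zeros in the low-intensity tail |

Volatile features draw a blank-side level (log2 ~ N(14, 2)) and a
specimen-vs-blank log2 fold difference from the configured two-component
mixture; per-sample values add N(0, `replicate_sigma`) log2 noise.
Protein features draw a log-normal base mean and linear-scale noise with
the planted power-law SD.  Three generator mechanisms keep the emitted
data faithful to their own declared statistics:

* **Sex effects are mean-preserving**: the favored sex is multiplied by
  `2·FD/(1+FD)` and the other by `2/(1+FD)`, so the between-sex ratio is
  FD while the pooled specimen mean — and hence the blank fold-difference
  mixture — is unchanged.
* **Dropout is feature-level**: features in the lowest
  `dropout_quantile` of median intensity get every cell zeroed with
  probability `dropout_rate`.  Zeroing specimen and blank cells at the
  same rate leaves the specimen/blank mean ratio unbiased; cell-level
  thresholding would selectively erase the blank traces of biological
  features and inflate the biological component mean.
* **Pairs live on abundant proteins** (above the dropout tail, as real
  carrier proteins are) and reuse each layer's own noise scale, so pair
  members are marginally indistinguishable from other features and the
  power-law fit is undisturbed.

Each planted sex effect carries a group scope — all three groups (30 %),
{MUS, wMUS} (40 %), or {DOM} (30 %) — so importance rankings correlate
strongly between the two *musculus* groups and weakly across subspecies,
mirroring the empirical pattern.  An optional `group_shift` multiplies
wMUS intensities to emulate an environment effect; it defaults to off
because no quantitative effect size is established.

**What the generator does not emulate:** retention times, spectra or
chemical identity; batch effects beyond the blank mechanism; repeated
collections per individual (each column is an independent sample);
missing-at-random intensity noise; correlation structure among non-pair
features.  Passing tests therefore demonstrate that the algorithms
recover the statistical structures they target at realistic scale and
noise — not that any specific biological dataset will show these effects.

## Problem sizes used in checks

The automated checks run the generator at study scale (1200 volatiles,
500 proteins, 54 specimens) across 20 seeds for the multi-seed rate
estimates, with 300–500 resampling iterations and 300-tree forests; the
end-to-end determinism check uses a reduced configuration (150 volatiles,
60 proteins, 4 specimens per cell).  Importance-rank similarity between
groups is computed over all 500 proteins rather than a curated
carrier-protein subset, so the absolute rho values are lower than a
subset analysis would give; the ordering (shared effects > disjoint
effects) is the tested property.

## Known limitations

* The mixture filter assumes exactly two normal components; heavy-tailed
  or multi-modal contamination profiles would need k > 2, which is out of
  scope.
* The resampled PLGEM null borrows noise from a single condition; strong
  heteroscedasticity *between* conditions beyond the power law is not
  modelled.
* The two-block correlation is reported per component without a
  permutation test; treat it as descriptive.
* `importance > 0.1` and `r > 0.62` are conventions inherited from the
  application domain, not universal thresholds.
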