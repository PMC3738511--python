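# Methods

## The experimental structure

A 12-plex two-channel slide hybridizes 24 RNA samples: each of the 12
sub-arrays ("arrays" throughout) carries one Cy3- and one Cy5-labeled
sample. Samples are laid out in a loop with dye swaps so that treatment
groups are separated from dye and array effects: `loopmix` interleaves the
groups round-robin before pairing consecutive samples onto arrays, which
guarantees that the two channels of every array come from different
groups. Sorting samples by group first — the obvious alternative — would
put both channels of each array in the same group and leave treatment
contrasts confounded with the array random effect, defeating the design.
Dye assignment within each pair is oriented greedily toward per-group
balance, which yields the canonical 4 Cy3 / 4 Cy5 split for 8-sample
groups and 3/3 for 6-sample groups; an odd total leaves the final Cy5
channel unused and the lone sample takes whichever dye balances its group.
Each transcript is printed as duplicate spots assigned to different layout
blocks.

`ArrayDesign` reports (but does not require) loop connectivity: with one
channel per sample the sample graph is a pairing, and designs with an
empty channel are legal.

## Filtering

Two spot-level filters run before any model: per-channel intensities below
the array background (default 300) are set missing, and a spot is dropped
when present on fewer than `min_present` (default 20) of the 2×`n_arrays`
sample-channels. "Present on 20 of 24 arrays" is read as *channels*
because the experiments of interest hybridize 24 samples; a per-array mode
(both channels required) is available via `count_mode="arrays"`. Filtering
is idempotent and monotone in the threshold. All downstream modeling is on
log2 intensities.

## The two-stage mixed model

**Stage 1 (normalization).** Over all spots jointly,

    Y = mu + dye + block + u_array + u_array:dye + u_array:block + e,

with dye (2 levels) and block fixed, and the three array terms independent
Normal random components. The model is fitted by REML; the carried-forward
quantity is the *conditional* residual `Y − Xβ̂ − Zû` (fixed-effect
prediction and BLUPs both removed), so dye bias, block offsets, and
array-level shifts — including their dye and block interactions — are
swept out before any gene-level testing.

**Stage 2 (per-transcript ANOVA).** For each transcript, on its residuals,

    r = mu + treatment + spot + dye + u_array + e,

with treatment (group), spot (duplicate index) and dye fixed and array
random. The headline test is the joint F-test of the treatment dummies,
`F = β̂ₜ' C⁻¹ β̂ₜ / q` with `C` the GLS covariance of the treatment
effects; all pairwise group contrasts are reported with t-tests from the
same covariance. Transcripts without at least two groups of two
observations are skipped with a reason code; underpopulated groups are
dropped from a transcript rather than dropping the transcript.

**Degrees of freedom.** Denominator df use the containment-style rule
`n − rank([X Z])`, which equals the classical ANOVA df in balanced designs
and reduces to the OLS residual df when the random effect is absent. This
matches the convention of the classical mixed-model ANOVA software this
pipeline emulates; a Satterthwaite approximation would require the
curvature of the REML surface for a calibration gain we could not detect —
under the global null the p-value distribution over 2,000 simulated genes
is uniform (KS statistic 0.023).

**Estimation.** Both models are variance-components models
`y = Xβ + Σ Z_k u_k + ε` with indicator `Z_k`. `loopmix.reml` profiles β
and the residual variance out of the REML criterion and evaluates the rest
through cross-products via the Woodbury identity, so one objective
evaluation costs O(q³) in the total number of random-effect levels
(q ≤ ~100 here) regardless of the number of observations, and the
per-transcript model (whose `Z'Z` is diagonal) collapses to closed-form
vector operations. Ratios σ²ₖ/σ²ₑ are optimized in log space — a grid plus
Brent refinement for one component, a lattice prescan plus Nelder–Mead for
several — with the zero boundary always compared explicitly, so null
components are reported as exact zeros and every reported variance
component is non-negative. Transcripts whose REML fit fails are refitted
as fixed-effects ANOVA and flagged (`fallback_fixed`). The engine is
cross-checked in the test suite against statsmodels `MixedLM` (and agreed
with R `lme4` to four digits during development).

**Multiple testing.** Benjamini–Hochberg step-up, applied separately per
family (the overall tests; each pairwise contrast). The
differential-expression call set defaults to the overall-test set;
`de_set="union-pairwise"` switches to the union of the contrast calls.

## Probe selection

The pilot-array ranking scores each candidate probe by its green-channel
intensity divided by the median intensity of all of the transcript's
probes (the probe under scoring included; the median of an even count is
the mean of the central pair). One probe: pass-through with a dual-dye
background QC flag. Two: the brighter. Three to six: the top ratio if
strictly below the cutoff (default 3), else the second — a ratio exactly
at the cutoff is treated as an outlier, and if the second ratio is also
high it is still chosen but QC-flagged (the rule table prescribes no
further fallback). Seven: when the top ratio strictly exceeds the cutoff,
that probe is removed once, ratios are recomputed over the remaining six,
and the new top ratio wins. Ties break to the earliest probe in input
order, making the selection order-stable; ratios are scale-free, so
rescaling a transcript's intensities never changes the choice.

## Downstream statistics

- **PCA**: SVD of the mean-centered samples×genes matrix (covariance
  scale — the inputs share the log2 scale, so no correlation rescaling).
  Each retained component is associated to the design factor with the
  largest R² of a one-way fit to its scores.
- **Clustering**: k-means (default k=2, 10 restarts, explicit seed) on
  row-standardized profiles; Ward linkage via scipy. All-identical rows
  short-circuit to a single cluster.
- **Set statistics**: Venn region counts for 2–3 sets; upper-tail
  hypergeometric overlap p with representation factor RF = k/(n₁n₂/N);
  two-sided Fisher's exact test; per-term hypergeometric enrichment with
  BH adjustment across terms and an optional EASE variant (tail computed
  at k−1, so single-gene hits are never significant). The enrichment
  background is an explicit, required argument — the recommended choice is
  the set of transcripts that entered the DE analysis.
- **Ancestor mapping**: single-count slim mapping — each input term adds
  exactly 1 to each of its mapped ancestors, unmapped terms land in an
  unassigned bucket, and duplicate input terms count twice (list
  semantics).
- **Two-count proportion test**: for an up/down split (a, b) the
  likelihood-ratio statistic G = 2[a·ln(2a/(a+b)) + b·ln(2b/(a+b))] is the
  headline, with the Pearson form alongside; for the published counts
  404/477 these give 6.06/6.05 — the value printed by the original
  analysis software (6.78) is not reproducible from the counts alone and
  is deliberately not targeted.
- **qPCR**: target values divided by the geometric mean of the
  housekeeping genes, optionally rescaled so the reference group's mean is
  1; groups compared by tie-corrected Kruskal–Wallis.

## The synthetic generator

`generate(EffectSpec)` draws log2 signal as

    baseline + transcript offset + treatment effect (DE transcripts)
    + dye + block + u_array + u_array:dye + u_array:block + residual

and exponentiates, so the log2 transform recovers the additive scale
exactly; missingness is injected completely at random. Defaults emulate
the study conditions at desk scale: three groups of eight samples on
twelve arrays, duplicate spots, a 1.0 log2 dye offset, fixed block offsets
(0, 0.3, −0.2, 0.1), array/array-dye/array-block SDs of 0.5/0.3/0.2,
residual SD 0.25, 10% DE transcripts with per-group effects drawn
N(0, 1.0), and a transcript-offset SD of 1.0 (about two-fold spread across
transcripts, conservative for expression data). Everything is
deterministic given `seed`. `generate_factor_matrix` plants two crossed
binary factors (environment/rank) at a chosen variance ratio for the PCA
partition tests; `generate_annotation` plants one enriched term for the
enrichment tests.

What the generator does *not* emulate — scanner saturation, spatial
gradients, probe-affinity differences, correlated missingness — bounds
what passing tests show: they validate the statistical machinery under the
stated model, not robustness to artifacts the model excludes.

## Verification scale and comparison targets

The replicate-based checks run at the published design scale (24 channels,
12 arrays) with sizes chosen to finish in minutes on one CPU: 500
transcripts per replicate, 100 replicates for error-rate checks, 20 seeds
for recovery medians. Two choices deserve explanation:

- *Variance-component recovery* compares the median estimate of the array
  and array×dye components to the median **realized** variance of the
  planted draws rather than to the population value: twelve draws from
  N(0, σ²) have a χ²₁₁-distributed sample variance (±40% per seed), so at
  this design scale the nominal value is not recoverable by any estimator,
  while the realized value is. The residual variance and the dye contrast,
  which every cell informs, are compared to their nominal values.
- *FDR control* is measured for the modeling pipeline
  (normalize → per-gene ANOVA → BH) on uncensored data.

## Known limitations

- **Background censoring biases near-threshold genes.** Masking cells
  below a fixed intensity censors a gene's low tail asymmetrically across
  groups; for transcripts whose expression straddles the background this
  manufactures spurious group differences, and in simulations with many
  near-background transcripts it inflates the empirical FDR of the
  downstream ANOVA (≈0.13 at a nominal 0.10). This is a property of
  threshold filtering itself. The presence filter removes the worst cases;
  treating censored cells as missing-at-random is still an approximation,
  and results for genes near background deserve skepticism in any
  pipeline of this design.
- The per-family BH adjustment assumes the usual PRDS-type positive
  dependence across genes; shared-array correlation widens the replicate-
  to-replicate spread of the false discovery proportion even while the
  mean is controlled.
- With 12 arrays, array-level variance components are estimated with ~11
  effective degrees of freedom; single-experiment component estimates are
  indicative, not precise.
- The enrichment module tests one term at a time against a user-supplied
  background; it does not reproduce fuzzy term clustering or any
  curated-background conventions of web annotation tools, so p-values are
  comparable across runs of this package but not across tools.
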