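# loopmix

Mixed-model analysis of two-color loop-design microarray experiments.

`loopmix` re-implements, as a tested and reusable Python library plus CLI,
the statistical pipeline used in socio-genomic expression studies of fire-ant
colony founding, where RNA from individual queens (solitary foundresses,
cooperative winners and losers) is hybridized on 12-plex two-channel
arrays in a loop design with dye swaps. The pipeline covers:

- **Pilot-array probe selection** — one oligo per transcript chosen from up
  to seven candidates by intensity/median-intensity ratio ranking, with
  outlier removal.
- **Spot filtering and log2 transform** — cells below the array background
  (default 300) are masked; spots present on fewer than 20 of 24
  sample-channels are dropped.
- **Two-stage mixed-model analysis** — a global normalization model

  `Y = μ + dye + block + array + array·dye + array·block + ε`

  (dye, block fixed; array terms random, fitted by REML with non-negative
  variance components), followed by a per-transcript ANOVA on the
  normalization residuals

  `r = μ + treatment + spot + dye + array + ε`

  (treatment/spot/dye fixed; array random) with an overall treatment
  F-test, all pairwise group contrasts, and Benjamini–Hochberg FDR control
  per test family.
- **Downstream statistics** — PCA variance partition with design-factor
  association, k-means and Ward clustering, Venn region accounting,
  hypergeometric overlap tests with representation factors
  (RF = k/(n₁n₂/N)), term enrichment with optional EASE correction and
  GO-slim single-count ancestor mapping, two-count proportion tests
  (likelihood-ratio G and Pearson), Fisher's exact test, and qPCR
  statistics (geometric-mean housekeeping normalization, Kruskal–Wallis).
- **A synthetic-data generator** that emulates the loop design (balanced
  dye swaps, duplicate spots, additive dye/block effects, Normal
  array-interaction components, planted treatment effects) with full
  ground truth, so every stage is testable without downloads.

## Worked example

```python
from loopmix import (EffectSpec, generate, filter_spots, log2_transform,
                     run_de)

spec = EffectSpec(n_transcripts=200, fraction_de=0.1,
                  treatment_effect_sd=1.0, baseline_mean=12.0, seed=1)
raw, design, truth = generate(spec)          # 3 groups x 8 queens, 12 arrays
filtered, report = filter_spots(raw, design)  # background 300, >=20/24 rule
de = run_de(log2_transform(filtered), design, q_threshold=0.001)
print(de.n_tested, len(de.significant),
      len(de.significant & truth.de_transcripts))
```

prints `199 13 13`: of 200 simulated transcripts one fell below the
presence filter, 13 were declared differentially expressed at FDR < 0.001,
and all 13 are genuinely differentially expressed (20 were planted; an
effect SD of 1.0 log2 unit leaves the weaker effects undetectable at this
stringency — raising `q_threshold` trades precision for recall).

The same run through the CLI:

```bash
loopmix run --config config.yaml --out-dir out
```

writes `design.txt`, `de_results.tsv`, `significant.txt`,
`normalization.json` (variance components `array 0.010`, `array_dye 0.162`,
`array_block 0.030`, `residual 0.967`; estimated dye contrast `0.733` log2
units for this realization) and `summary.json` (PC1 of the significant
genes explains `71.6%` of the sample variance and tracks the treatment
factor). Every output carries a provenance header with the package
version, seed and config hash; re-running the same config is
byte-identical. Individual stages are also exposed (`loopmix simulate`,
`select-probes`, `preprocess`, `normalize`, `de`, `pca`, `cluster`,
`overlap`, `enrich`, `qpcr`).

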