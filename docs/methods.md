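# Methods

## Model and assumptions

The pipeline treats DNA methylation as gene-level multivariate signals. A
gene's CpG sites in a cohort form a samples × sites matrix; PCA reduces it
to the leading score columns holding ≥ `var_retained` (default 0.9) of the
variance, capped at n_samples − 1 components so the subsequent canonical
correlation stays well-posed (CCA needs more samples than combined
components to be estimated stably). An edge of the prior gene regulatory
network is weighted by the first canonical correlation between the two
genes' score blocks — the largest correlation attainable between any linear
combination of one gene's components and any of the other's. Because
canonical correlations depend only on the two column spaces, the weight is
invariant to component scaling and rotation; this is the property the test
suite checks against an independent generalized-eigenvalue implementation.
CCA returns min(p, q) canonical correlations; the edge weight is the first
(largest) by default, the mean being available via `cca_method="mean"`.
Within-block covariances are ridged by 1e-8 · trace/p only when
near-singular, so the invariance holds to machine precision on
well-conditioned blocks.

Modules are detected on the largest connected component by multilevel
(Louvain) maximization of weighted modularity, with the sweep order seeded
for reproducibility. The reported Q is classic weighted modularity; the
package's own `modularity()` recomputes it by direct double summation and
acts as the oracle for the detector. Edge weights enter unthresholded.

Module eigengenes are the first principal component of a module's
*significant* sites (two-group p < .05; set `sig_alpha=1` to use all
sites), sign-fixed to correlate non-negatively with the module's mean β so
"higher eigengene" reads as "more methylated". Module–trait association
uses Spearman's ρ because the traits (event, M, N, T stages) are ordinal;
module membership (MM) uses Pearson correlation with the eigengene, the
convention of eigengene-based network analysis. Both are configurable.

Survival screening is deliberately nonparametric: median β split, the
Kaplan–Meier product-limit estimator, and the two-sample log-rank test with
the hypergeometric variance and no continuity correction (matching
`survival::survdiff`'s default). Ties at the median go to the "low" arm.

## Analysis population

Clinical indicators and survival exist only for tumours, so after the
differential stage the network weighting, eigengenes, trait association and
survival run on case samples by default (`analysis_samples="case"`).
Pooling cases and controls would let the global case/control methylation
shift dominate every first principal component and every CCA weight,
turning all modules into proxies of tumour status. The pooled alternative
remains available.

## Key tunable parameters

| parameter | default | meaning |
|---|---|---|
| `zero_policy` | any | drop a site if any (vs all) sample has β = 0/missing |
| `cut_height_quantile` | 0.99 (pipeline), 0.95 (op) | sample-tree cut for outlier removal |
| `fc_threshold`, `p_threshold` | 0.235, 0.05 | DMP gates, |log₂ FC| > |log₂ 0.235| and p < .05 |
| `var_retained` | 0.9 | per-gene PCA cumulative variance |
| `resolution` | 1.0 | modularity null-model scaling (1.0 = classic Q) |
| `min_module_size` | 100 | retention floor after detection |
| `mm_threshold`, `gs_threshold` | 0.85, 0.17 | key-site screen (strict inequalities) |
| `split_quantile` | 0.5 | high/low methylation split for survival |

The published gates (0.235/.05, 0.85/0.17 with a 0.75/0.15 alternative for
a second module, 100-gene floor) are the defaults; the 100-gene floor
belongs to networks of thousands of genes and is lowered explicitly when
analysing small synthetic cohorts. The fold change is the case/control
ratio of mean β by default; whether such a threshold is a β-ratio or a Δβ
is ambiguous in common usage, so `fc_mode="delta"` switches the gate to
|Δβ| > threshold. The p gate uses raw p values by default ("P < .05"
semantics); `use_adjusted_p` switches it to BH-adjusted values. The
`dmg_policy` for restricting the prior network is "both" endpoints
differentially methylated, with "either" available.

Outlier detection follows the sample-tree convention: Euclidean distance,
average linkage, cut at a quantile of the merge heights, keep the largest
cluster. On data with strong latent-factor structure the 0.95-quantile cut
can shear off whole lobes of the sample cloud rather than stragglers, so
the pipeline default is 0.99, which removes only a handful of samples from
a 140-sample synthetic cohort — the scale a cohort analysis reports — while
the standalone operation keeps the conventional 0.95.

## The synthetic generator

`generate_dataset` emulates the statistical skeleton the analysis assumes:
module latent factors z ~ N(0,1) per sample; site signal
a·z + ε with loading a = 0.8 and noise sd 0.3 (site R² to its factor
≈ 0.88), mapped through the logistic function and clipped to [0.01, 0.99];
a prior network with p_in = 0.3 within and p_out = 0.02 between modules;
an ordinal nodal-stage trait built as a discretized noisy monotone function
of one module's factor calibrated to Spearman ρ ≈ 0.5; exponential survival
whose hazard doubles (HR = 2) above the prognostic site's median β, with
independent exponential censoring leaving ≈ 90% events; and per-gene
expression anti-correlated (ρ ≈ −0.5) with the gene's first site. All draws
come from sub-streams spawned from one seed, so datasets are bit-reproducible
and component-wise independent.

Planted DMP sites are modelled as promoter hypermethylation: a low baseline
(β ≈ 0.03) gaining Δβ = 0.3 in cases. The low baseline is deliberate twice
over. First, a ~4.3× β-ratio gate is only reachable from a low baseline —
a 0.3 shift at β = 0.5 never passes it. Second, the group mean of a
logistic-normal site is convexity-inflated above its baseline by the
factor variance, so the baseline must leave headroom for the ratio to
clear the gate after inflation.

Cohort defaults (120 cases / 20 controls) were fixed by a design-time power
analysis: with ≈ 90% events and the planted HR of 2, the median-split
log-rank test retains ≥ 95% power after expected outlier attrition, so
end-to-end recovery tests measure correctness of the pipeline rather than
statistical luck at the margin of detectability.

What the generator does **not** emulate: Illumina probe-type chemistry and
normalization artefacts, CpG-island spatial correlation, cell-type
mixtures, batch effects, or realistic co-methylation decay along the
genome. Passing tests therefore demonstrate that the algorithms recover the
structure they model, not that the pipeline is robust to those real-data
complications.

## Numerical choices and degenerate inputs

* PCA and eigengenes via SVD of the centered matrix; eigengene sign fixed
  against the module's mean β; a constant gene yields a zero block that the
  CCA stage rejects explicitly.
* CCA weights are clipped to [0, 1]; sample order is asserted identical
  between blocks; n ≤ p + q triggers a warning, not an error.
* Sites constant across samples get missing MM/GS and fail the screen;
  constant traits produce missing association cells with a warning.
* Both-groups-constant sites get t = 0, p = 1 with a warning rather than an
  error, so null fixtures with flat rows survive.
* Log-rank with zero total events degenerates to χ² = 0, p = 1 with a
  warning; the variance term guards n = 1 risk sets.
* BH adjustment preserves input order and clips at 1; module indices are
  re-assigned 1..k by descending size with ties broken by the
  lexicographically smallest member, making partitions deterministic.

## Problem sizes used in the checks

The test suite and the acceptance script run on synthetic cohorts of 480
sites × 140 samples (120 genes in four 30-gene modules, four sites per
gene), batches of 5–20 seeds, and module-detection benchmarks of 120-node
planted networks — sizes at which every stage's behaviour is already
measurable and the full suite completes in well under a minute per batch.
The published cohort-scale quantities (hundreds of thousands of sites,
a 4,719-gene component, 20 modules at Q = 0.59) depend on the original
tumour matrix and are not reproducible from synthetic data; the package
documents them as context, not as test targets.

## Known limitations

* Welch t-tests per site, not moderated (limma-style) variance shrinkage;
  at cohort-scale n the two agree asymptotically, but for very small groups
  moderation would be more powerful.
* The first canonical correlation between low-dimensional blocks is upward
  biased at small n (max over directions); weights are comparable within a
  cohort but not across cohorts of different size.
* Single median split and univariate log-rank per site — no multivariate
  survival modelling, no multiple-testing control across key sites (the
  screen mirrors the published procedure).
* The module count and Q of any given run depend on the Louvain sweep
  order; fixing the seed makes runs reproducible but does not remove the
  algorithm's intrinsic degeneracy between near-optimal partitions.
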