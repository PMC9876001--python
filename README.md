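# methccanet

Weighted gene-network analysis of DNA methylation cohorts: from a 450K-style
site × sample β matrix and a prior gene regulatory network to gene modules,
module–trait associations, key CpG sites and their prognostic value.

## The problem and the method

Tumour methylomes carry coordinated methylation changes across functionally
related genes. This package reconstructs that coordination as a **weighted
gene regulatory network** and walks it down to single prognostic CpG sites:

1. **Cleaning** — failed probes (β = 0 or missing) are removed, outlying
   samples are dropped from a hierarchical sample tree, and the methylation
   and clinical tables are aligned.
2. **Differential methylation** — every site gets a Welch t-test between
   case and control groups; sites with |log₂ FC| > |log₂ 0.235| and
   p < .05 are DMPs, and genes carrying one are DMGs.
3. **CCA edge weighting** — each gene's sites are PCA-reduced to a feature
   block X (samples × components, ≥ 90% variance retained); each prior
   edge between DMGs is weighted by the **first canonical correlation**

   ρ₁(X, Y) = max over a, b of corr(Xa, Yb)
            = σ₁( Σxx^(−1/2) Σxy Σyy^(−1/2) ),

   invariant to how either gene's components are scaled or rotated.
4. **Modules** — the largest connected component is partitioned by
   multilevel (Louvain) maximization of weighted modularity
   Q = (1/2m) Σᵢⱼ [wᵢⱼ − kᵢkⱼ/2m] δ(cᵢ, cⱼ); modules with < 100 genes are
   discarded (configurable).
5. **Trait association** — each module's eigengene (first PC of its
   significant sites) is correlated with ordinal clinical traits (event,
   age, M, N, T) by Spearman's ρ.
6. **Key sites** — within the trait-linked module, sites with module
   membership |MM| > 0.85 (Pearson vs the eigengene) and gene significance
   |GS| > 0.17 (Spearman vs the trait) are key sites.
7. **Survival** — each key site splits tumours at its median β; the two
   arms are compared by Kaplan–Meier curves and the log-rank test.

A synthetic-data generator (`methccanet.synthetic`) draws complete cohorts
with planted modules, DMPs, a module-linked nodal-stage trait and a
prognostic site with a known hazard ratio, so every stage can be scored
against ground truth without any download.

## Worked example

```bash
python examples/06_full_pipeline.py
```

```
sites retained: 480, samples: 138
DMPs: 240, DMGs: 120, network genes: 120
modules: 4 (Q = 0.728), target module: m1
key sites: 60, survival-flagged: 21
recovery vs planted truth: {'module_ari': 1.0, 'dmp_precision': 1.0,
 'dmp_recall': 1.0, 'prognostic_site_selected': 1.0,
 'trait_top_module_rho': 0.506, 'trait_sign_consistent': 1.0}
```

All 240 planted DMPs are recovered, the four planted 30-gene modules are
partitioned exactly (adjusted Rand index 1.0, modularity 0.728), the module
driving nodal stage tops the association table at ρ ≈ 0.51 (target 0.5),
and the planted prognostic site survives the MM/GS screen and is flagged by
the log-rank test. `examples/01`–`05` run each stage separately with the
same kind of commentary.

The same pipeline runs from the shell on the standard file formats:

```bash
methccanet simulate --seed 1 --out data/
methccanet run --beta data/beta.tsv --annot data/annotation.tsv \
    --clinical data/clinical.tsv --prior data/prior_network.csv --out run1/
```

`run1/manifest.json` records per-stage counts, the parameter hash and the
seed; all intermediates are plain TSV/JSON.

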