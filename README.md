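# shapstrat

SHAP-space patient stratification for immunotherapy cohorts.

Immune-checkpoint-inhibitor response in metastatic urothelial carcinoma (and
other solid tumours) is heterogeneous: binary responder / non-responder labels
hide subgroups with distinct biology and prognosis, and conventional
clustering of expression profiles separates them poorly. `shapstrat`
implements an interpretable stratification framework for bulk transcriptomic
cohorts with RECIST response annotations:

1. **DEG selection** — responder vs non-responder differential expression
   with the empirical-Bayes moderated t-statistic
   (t̃_g = logFC_g / (s̃_g √(1/n₀+1/n₁)), s̃²_g = (d₀s₀² + d_g s²_g)/(d₀+d_g)),
   Benjamini–Hochberg FDR, and gates FDR < 0.05, |FC| > 1.3.
2. **Attribution extraction** — an XGBoost classifier is trained on the DEG
   features; per-patient SHAP values φ_ij (path-dependent TreeSHAP, margin
   scale, satisfying base + Σ_j φ_ij = margin_i) form a patients × genes
   attribution matrix that serves as the clustering feature space.
3. **SHAP-space clustering** — PCA on the attribution matrix, a shared
   nearest-neighbour (SNN) graph with dynamically chosen k
   (k = clamp(round(0.05·N), 5, 50); edge weight = |kNN(i) ∩ kNN(j)|),
   normalized spectral clustering with the cluster count chosen by the
   eigengap, and optional recursive sub-clustering of heterogeneous clusters.
4. **Stability analysis** — repeated 90% subsampling with full re-training,
   Hungarian matching of replicate clusters to the reference, adjusted Rand
   index, and per-cluster response-distribution summaries.
5. **Characterisation** — per-cluster response/PD-L1/immune-phenotype/TMB/
   mutation/gene-panel profiles, Kaplan–Meier curves and log-rank tests, and
   a 7-factor composite immunogenomic score (five activation factors scored
   +1: PD-L1 high, excluded/inflamed phenotype, TMB high, CXCL13 high, TP53
   mutant; two suppression factors scored −1: TGFB1 high, FGFR3 mutant) with
   quartile grouping.

A synthetic-cohort generator with four planted immune subclasses (expression
modules, response probabilities, mutations, censored survival) makes every
stage testable without external downloads.

## Worked example

```sh
shapstrat simulate --n 300 --seed 1 --out cohort/
shapstrat run-all --expr cohort/expr.csv --clinical cohort/clinical.csv \
    --mutations cohort/mutations.csv --seed 1 --out run/
```

which logs

```
INFO shapstrat: DEG selection: 26/195 genes pass FDR<0.05, FC>1.3
INFO shapstrat: clustering: m=17 PCs, k_nn=15, k=4 clusters
{
  "n_feature_genes": 26,
  "k_clusters": 4,
  "mean_stability_ari": 0.792
}
```

26 of 195 genes pass the DEG gates (the planted TGF-β and T-cell-activation
modules), the eigengap finds the four planted subclasses directly
(`run/clusters.csv` holds per-patient labels; the adjusted Rand index
against the planted truth is 0.87), and ten 90%-subsample replicates agree
with the full-cohort clustering at a mean ARI of 0.79 with per-cluster
response distributions shifting by at most a few percentage points
(`run/stability.json`). `run/cluster_profile.tsv` tabulates per-cluster
response rates, immune phenotypes, mutation frequencies and panel means;
`run/composite_scores.csv` holds each patient's composite score (range −2…+5)
and quartile group.

The same stages are available as library functions (`shapstrat.run_pipeline`,
`shapstrat.differential_expression`, `shapstrat.shap_matrix`, …) and as
individual subcommands (`deg`, `shap`, `cluster`, `stability`,
`characterize`, `score`). A `--gene-list` option restricts the feature space
to a fixed gene panel for external-validation cohorts.

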