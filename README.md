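# cohub — co-expression hub-gene discovery

`cohub` is a reusable Python implementation of a systematic framework for
finding **phenotype-associated hub genes** in case/control gene expression
studies collected across several microarray platforms, of the kind used to
dissect endometrial cancer (EC) grade, histological type and stage.

The pipeline:

1. **Merge & normalize** — platforms are intersected on shared gene
   identifiers and each gene is standardized within platform (mean 0,
   SD 1), which removes gene-wise affine platform effects exactly.
2. **Differential expression** — two-sample t test (Welch by default)
   case vs. control per gene with Benjamini–Hochberg FDR control; the
   network gene set is the union of DE genes (`q < 0.05`, fold change
   > 1.5) and the highest-variance remainder up to a target count.
3. **Weighted co-expression network (WGCNA-style)** — adjacency
   `a_ij = |cor(x_i, x_j)|^β` (β from the scale-free-topology fit, with
   robust fallbacks), topological overlap

   `TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,

   average-linkage clustering of `1 − TOM`, and a static cut at height
   0.95 with minimum module size 100. Each module is summarized by its
   **eigengene** (first principal component), correlated with each trait
   (Bonferroni-adjusted), and each gene gets a scaled intramodular
   connectivity `K = k_i / max_j k_j` and a gene significance
   `GS = |cor(x_i, trait)|`.
4. **Hub triage** — for each trait-associated module, the member genes
   enter a bootstrap **elastic-net logistic regression** (B = 1000
   resamples, penalty chosen per resample by internal cross-validation);
   `f` counts the resamples in which a gene's coefficient is nonzero. A
   (gene, trait) pair is a hub when `f > 750`, `K > 0.25` and `GS > 0.2`
   (strict inequalities).
5. **Classifier** — the hub signature feeds an elastic-net classifier
   evaluated by stratified 10-fold cross-validation, with ROC/AUC and a
   label-permutation p-value.
6. **Enrichment** — hypergeometric over-representation of each module
   against any GMT gene-set collection.

A first-class **synthetic study generator** plants the structure this
analysis assumes — latent-factor modules, designated hubs with elevated
loadings, logistic trait effects, case/control shifts, per-platform
affine distortions — together with the ground truth needed for recovery
testing.

The package ships `src/cohub/data/ec_hub_genes.tsv`, a transcription of
the published 19-entry endometrial-cancer hub-gene score table (gene,
trait, module, f, K, GS), used as the reference input for the triage
rule.

## Worked example

```python
import numpy as np
from cohub import SyntheticConfig, generate_synthetic_study, CoexpressionAnalysis
from cohub.preprocess import (intersect_by_gene_id, standardize_within_platform,
                              merge_platforms, t_test_de, select_network_genes)

matrix, phenotypes, truth = generate_synthetic_study(SyntheticConfig(seed=7))
platform = np.asarray(matrix.platform)
parts = [matrix.subset_samples(platform == p) for p in matrix.platforms]
merged = merge_platforms([standardize_within_platform(m)
                          for m in intersect_by_gene_id(parts)])
phenotypes = phenotypes.align(merged.sample_ids)

de = t_test_de(merged, phenotypes.status)
print("DE genes at 1% FDR:", sum(r.q_value < 0.01 for r in de))
genes = select_network_genes(de, merged, fdr_cut=0.05, fc_cut=1.5, target_n=450)

results = CoexpressionAnalysis(merged.subset_genes(genes), phenotypes).fit()
print(results.summary())
```

prints

```
DE genes at 1% FDR: 451
Weighted co-expression network analysis
===============================================
genes: 450   samples: 300   soft power beta: 6 (unsigned)
static cut: height 0.95, min size 100
modules: 3 (unassigned genes: 47)
  M1 (turquoise): 150 genes
  M2 (blue): 149 genes
  M3 (brown): 104 genes

module-trait correlations (Pearson r, Bonferroni-adjusted p):
    M1 x grade  r=+0.588  p_adj=8.20e-11  (n=112)
    M1 x type   r=-0.111  p_adj=1.00e+00  (n=112)
    M1 x stage  r=+0.096  p_adj=1.00e+00  (n=112)
    M2 x grade  r=-0.026  p_adj=1.00e+00  (n=112)
    M2 x type   r=+0.005  p_adj=1.00e+00  (n=112)
    M2 x stage  r=+0.592  p_adj=5.46e-11  (n=112)
    M3 x grade  r=-0.007  p_adj=1.00e+00  (n=112)
    M3 x type   r=+0.538  p_adj=8.48e-09  (n=112)
    M3 x stage  r=+0.020  p_adj=1.00e+00  (n=112)
```

The three planted modules are recovered intact; each one's eigengene
correlates specifically with the trait its latent factor drives
(`r ≈ 0.54–0.59`, everything else near zero). From here,
`cohub.hubs.run_hub_selection(results, ...)` screens the trait-relevant
modules with the bootstrap elastic net and applies the (f, K, GS) cuts,
and `cohub.classify.crossvalidated_roc(...)` evaluates the resulting
signature.

The same pipeline is available from the shell:

```sh
cohub simulate --seed 7 --out study/
cohub run-all --seed 7 --out run/           # full pipeline + manifest.json
cohub triage                                # (f, K, GS) cuts on the shipped hub table
```

## Layout

| path | contents |
| --- | --- |
| `src/cohub/datatypes.py` | `ExpressionMatrix`, `PhenotypeTable`, `GeneSetCollection`, `HubScoreRow` |
| `src/cohub/io.py` | TSV / GMT readers and writers, shipped hub-table fixture |
| `src/cohub/simulate.py` | synthetic multi-platform study generator + ground truth |
| `src/cohub/preprocess.py` | merge, standardize, t-test DE, BH-FDR, network-gene choice |
| `src/cohub/network.py` | WGCNA core; `CoexpressionAnalysis` → `CoexpressionResults` |
| `src/cohub/elasticnet.py` | elastic-net logistic regression (coordinate descent) |
| `src/cohub/hubs.py` | bootstrap selection frequency f, (f, K, GS) triage |
| `src/cohub/classify.py` | stratified CV, ROC/AUC, permutation p-values |
| `src/cohub/enrichment.py` | hypergeometric gene-set over-representation |
| `src/cohub/pipeline.py`, `cli.py` | orchestration, manifest, `cohub` CLI |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
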