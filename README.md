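# sepira

Tissue-specific transcription-factor (TF) regulatory-network inference and
per-sample TF **activity** estimation from gene expression or promoter DNA
methylation.

## The problem

The expression level of a TF's own transcript is a poor proxy for whether
the TF is actually *doing* anything: activity depends on protein level,
localization, cofactors and chromatin context. A more robust readout is the
coherent behavior of the TF's **regulon** — the set of genes it activates or
represses. This package implements a two-stage procedure for regulatory
systems biologists working with multi-tissue bulk expression compendia and
Illumina 450k/EPIC-style methylation data:

1. **Network inference** (`RegulonInference` / `sepira build`). From a
   genes × samples log₂ expression compendium spanning many tissues, a
   signed bipartite TF → target network specific to one target tissue is
   reverse-engineered:
   * variance filter (sample SD ≥ 0.25);
   * Pearson correlation of every TF with every non-TF gene, with
     significance from the Fisher transform *z* = atanh(ρ) under
     N(0, 1/√(n_T − 3)), where **n_T is the number of distinct tissues**
     (the effective sample size — samples within a tissue are correlated),
     at the Bonferroni level α/(n_TF · n_gene);
   * partial-correlation pruning: for each gene claimed by ≥ 2 TFs, the
     partial correlation with each TF given the others (precision-matrix
     method) must stay ≥ 0.2;
   * TFs must keep ≥ 10 targets, before and after pruning;
   * tissue-specificity selection by two moderated-*t* contrasts
     (empirical-Bayes shrunken variances): target tissue vs all other
     tissues (p < 0.05, log₂FC > 1) **and** target tissue vs immune-rich
     "guard" tissues such as blood and spleen (p < 0.05, log₂FC > 1.5), the
     latter rejecting immune-cell markers picked up through immune
     infiltration of the target tissue.

2. **Activity scoring** (`TFActivityScorer` / `sepira activity`). For each
   sample, the z-normalized profile over all network genes is regressed on a
   TF's binding profile (+1 activated target, −1 repressed, 0 otherwise);
   the slope *t*-statistic is that TF's relative activity in that sample.
   With promoter methylation, gene-level values (mean beta over TSS200
   probes, falling back to first-exon then TSS1500 probes) are regressed on
   the **sign-reversed** network, since TF binding accompanies promoter
   hypomethylation.

Supporting machinery: differential activity (pooled *t* or rank-sum),
target-randomization nulls preserving per-TF regulon sizes and sign
multisets, Fisher-exact target-set enrichment with Monte-Carlo verification
and Benjamini–Hochberg adjustment, and a synthetic-data generator with
planted ground truth so the whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from sepira import (SimConfig, simulate_expression, BuildParams, build_network,
                    zscore_genes, infer_activity, differential_activity)

cfg = SimConfig(seed=1)                      # 10 tissues x 10 samples
expr, truth = simulate_expression(cfg)       # planted regulons + activities
tf_list = [g for g in expr.gene_ids if g.startswith("TF_")]

net, report = build_network(expr, tf_list, BuildParams(target_tissue="lung"))
print(report)

z = zscore_genes(expr, net.all_targets())
act = infer_activity(z, net)                 # TF x sample t-statistics
lung = [s for s in expr.sample_ids if expr.tissues[s] == "lung"]
immune = [s for s in expr.sample_ids if expr.tissues[s] in ("blood", "spleen")]
print(differential_activity(act, lung, immune, method="t").round(4))
```

prints (abridged)

```
{'n_genes_input': 460, 'n_genes_after_variance_filter': 410,
 'n_tfs_tested': 10, 'per_test_alpha': 1.25e-05, 'n_tissues': 10,
 'n_tfs_after_first_min_target_filter': 5, 'n_tfs_after_pruning': 5,
 'n_tfs_tissue_specific': 3, 'n_tfs_final': 3, 'n_targets_final': 120,
 'n_edges_final': 120, 'n_edges_positive': 114, 'n_edges_negative': 6}

            statistic  p_value  adjusted_p
TF_SP01       11.4079      0.0         0.0
TF_SP02        7.7811      0.0         0.0
TF_SP03        6.2409      0.0         0.0
```

The build recovered exactly the 3 planted lung-specific TFs (the 2 planted
immune confounders and 5 background TFs were rejected), 120 edges of which
114 positive, and all three are significantly more active in lung than in
the immune tissues. Against the planted truth, the inferred activities
correlate at r = 0.843, 0.846 and 0.839 across the 100 samples.

The same steps are available from the shell:

```bash
sepira simulate --seed 1 --outdir fixtures/
sepira build --expr fixtures/expr.tsv --tissues fixtures/tissues.tsv \
             --tfs fixtures/tfs.txt --target-tissue lung --out net.tsv \
             --report report.json
sepira activity --mode expression --expr fixtures/expr.tsv --net net.tsv --out act.tsv
sepira activity --mode dnam --betas fixtures/betas.tsv \
                --annotation fixtures/annotation.tsv --net net.tsv --out act_dnam.tsv
```

scikit-learn users can drive the same machinery through
`RegulonInference(tf_ids=..., target_tissue=...).fit(X, tissues)` and
`TFActivityScorer(network=net).fit_transform(X)` with `X` samples × genes;
both estimators support `get_params`/`set_params`/`clone` and pipelines.

## Documentation

See `docs/methods.md` for the model, its assumptions, the numerical
choices, what the simulator does and does not emulate, and known
limitations.
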