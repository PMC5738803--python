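# Methods

## Model

A TF's regulatory influence is summarized by a signed binding profile over
genes: +1 for targets it activates, −1 for targets it represses, 0
otherwise. Two quantities are estimated.

**The network.** Across a multi-tissue compendium, a TF and its genuine
targets co-vary because the TF's activity differs between tissues (and
between samples within a tissue). The build treats a gene as a candidate
target of a TF when their Pearson correlation is significant under a
deliberately conservative null: the Fisher transform z = atanh(ρ) is
compared to N(0, 1/√(n_T − 3)) with n_T the number of **distinct tissues**,
not the sample count. Samples of the same tissue are strongly correlated,
so the tissue count is the honest effective sample size; using it also
raises the bar for significance. n_T is always recomputed from the supplied
tissue labels. Candidate edges then face three further filters: a
Bonferroni family-wise threshold over all TF × gene tests, a partial
correlation ≥ 0.2 given all rival TFs of the gene (computed from the
precision matrix of the [gene, TF₁..TF_k] correlation matrix), and a
minimum of 10 surviving targets per TF (applied both before and after
pruning). Finally only TFs over-expressed in the target tissue are kept,
by two moderated-t contrasts: vs all other tissues (p < 0.05, log₂FC > 1)
and vs designated guard tissues (p < 0.05, log₂FC > 1.5). The guard
contrast exists because solid tissues carry infiltrating immune cells:
an immune-cell TF looks "tissue-specific" against the average of all
tissues but not against blood or spleen.

**Activity.** Per sample, the z-normalized profile over all network genes
is regressed (OLS with intercept) on one TF's binding profile; the slope
t-statistic is the activity score. The regression is univariate by design:
multiple regulation was already resolved during network construction, and
the 0-entries of the binding profile give every score the same gene basis.
With an intercept, the slope t equals r·√((G−2)/(1−r²)) for the Pearson
correlation r between profile and binding vector over the G network genes;
the implementation uses this identity, vectorized over TFs and samples.
Scores are **relative to the cohort** used for z-scoring — they support
within-dataset contrasts, not absolute cross-dataset comparison.

**Methylation mode.** Promoter methylation anti-correlates with TF binding
at activating targets. Gene-level promoter values are the mean beta over
TSS200 probes; genes lacking TSS200 probes on the array fall back to
first-exon probes, then TSS1500 probes (the fallback is a property of the
array design, decided per gene, not per sample; the phrase "1500 bp
upstream" is read as upstream of the TSS). The same regression then runs
on the sign-reversed network, so that higher activity again yields a more
positive score. We treat the region classes of the annotation table as
authoritative rather than recomputing distances from coordinates.

## Moderated t-test

The two-group contrasts use an empirical-Bayes moderated t: gene-wise
pooled variances s²_g (d residual df) are shrunk toward a common prior,
s̃²_g = (d·s²_g + d₀·s₀²)/(d + d₀), with (s₀², d₀) obtained by matching the
first two moments of log s²_g to the log-chi-square expressions
(digamma/trigamma identities; d₀ solved with a Newton iteration on the
trigamma inverse). p-values come from a t distribution on d + d₀ df,
capped at the total pooled df. When the observed spread of log-variances
does not exceed chi-square sampling noise, d₀ = ∞ and all genes share s₀².
With d₀ = 0 the statistic reduces to the ordinary pooled t (exposed via the
`prior_df` override, used in tests). The implementation was checked once
against the standard Bioconductor implementation on a frozen 200-gene
fixture; agreement is ~1e-15 on t, p and log-fold-change (the frozen
reference lives in `tests/data/`).

## Null models and enrichment

* **Target randomization** re-draws each TF's targets uniformly (without
  replacement) from a user-supplied gene universe excluding the TFs,
  preserving the per-TF target count and, by default, the per-TF multiset
  of edge signs (`preserve_signs=False` resamples signs with replacement).
  This is the stricter null; preserving only counts is available because
  sign preservation is a design choice, not a mathematical necessity.
* **Empirical p-values** use the add-one convention
  p = (1 + #extreme)/(1 + n): p is never zero, and an observation below
  all of 1000 nulls reports p = 1/1001 < 0.001.
* **Enrichment** of a regulon in an external target list (e.g. ChIP-seq
  peaks) is a one-tailed Fisher exact test on the 2×2 table within a stated
  universe, with a Monte-Carlo verification drawing equal-size random
  target sets; BH adjustment is applied across TFs.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `sd_min` | 0.25 | variance-filter floor on per-gene sample SD (log₂ units); inclusive |
| `alpha_fwer` | 0.05 | family-wise level; per-test level is α/(n_TF·n_gene) |
| `pcor_min` | 0.2 | partial-correlation floor; inclusive (values < 0.2 are zeroed) |
| `min_targets` | 10 | regulon-size floor, applied before and after pruning; inclusive |
| `de_p` | 0.05 | raw (unadjusted) p ceiling of both tissue contrasts |
| `lfc_all` / `lfc_guard` | 1.0 / 1.5 | log₂FC floors of the two contrasts (strict >) |
| `guard_tissues` | blood, spleen | immune-rich comparison tissues; `()` disables the guard explicitly |
| `min_overlap` | 10 | minimum measured targets for a TF to be scored |

All boundaries ("at least", "< 0.2 set to zero") are implemented inclusively
as written above. The contrast p-values are intentionally unadjusted: the
selection is a two-condition AND, and the thresholds are part of the recipe
rather than inference claims.

## Numerical choices

* Standard deviations and z-scores use the sample (n−1) convention
  throughout.
* Correlation p-values are two-sided (both correlation and
  anti-correlation count); ρ = ±1 maps to p = 0 and survives any threshold.
* Zero-variance genes get ρ = 0 (no edge) in the screen and all-zero rows
  (neutral) in the activity regressions, keeping the binding-profile
  alignment identical across samples; degenerate regressions (constant
  covariate or response) score 0 rather than NaN.
* Singular or under-determined correlation sub-matrices in the pruning step
  fall back to the Moore–Penrose pseudo-inverse with a warning.
* Missing beta-values are excluded pairwise from probe averaging and gene
  z-scoring; a gene-sample cell with no informative probe stays missing and
  that sample's regression simply drops the gene.
* Genes claimed by a single TF are exempt from pruning (the conditioning
  set would be empty), so an extreme `pcor_min` does not erase a network
  whose genes have unambiguous regulators.
* Duplicate row ids on input are collapsed by averaging before analysis.
* All outputs order TFs and targets lexicographically; builds are
  byte-reproducible.

## The synthetic-data generator

`simulate_expression` encodes exactly the structure the method exploits,
with planted ground truth: latent per-sample TF activities drive signed
target responses (x_g = sign·effect·a_t(s) + noise), TF transcripts track
their own activity, and the compendium contains immune-confounder TFs
(active in target and guard tissues), background TFs with no regulon,
free noise genes, and near-constant genes for the variance filter.
`simulate_dnam` emits 1–3 TSS200 probes per target whose betas are
inverse-logit(b₀ − sign·effect·a_t(s) + noise), plus fallback-only genes
(FirstExon / TSS1500) and pure-noise decoy probes.

Default conditions: 10 tissues × 10 samples, 3 tissue-specific TFs with 40
signed targets each (5% repressed, matching the published network's shape
of ~1438:73 positive:negative edges and ~47 targets/TF scaled down), gene
noise SD 0.5, DNAm noise SD 0.3. The free parameters were set once from
design analysis: activation level 3 (log₂ scale) with heterogeneity SD 0.5
where a TF is active and **zero basal activity elsewhere**, target effect
size 2, TF-transcript coupling 1.5 with transcript noise SD 0.2, and each
specific TF active in the target tissue plus two private secondary
tissues. The reasoning: (i) at this scale the effective-sample-size
Bonferroni null only admits marginal correlations ≳ 0.93, so a detectable
planted regulon must encode TF–target correlations around 0.95; (ii) TFs
active in identical tissue sets have collinear profiles, which defeats
partial-correlation disambiguation — private secondary tissues (the
realistic case: tissue-enriched TFs are rarely exclusive to one tissue)
decorrelate them; (iii) the per-sample t-statistic is scale-free, so any
basal regulon fluctuation in "inactive" samples is amplified into large
spurious scores — biologically, an unexpressed TF has no activity, hence
basal 0.

What the generator does **not** emulate: empirical expression distributions
of real compendia (library-size artifacts, count noise, batch effects),
unbalanced tissue sizes, overlapping regulons, indirect (cascade)
regulation, copy-number or cell-composition confounding, and probe-level
artifacts beyond sporadic missingness. Passing tests therefore demonstrate
correctness and calibration of the machinery under the stated generative
assumptions, not performance on real cohorts.

## Problem sizes used in validation

The shipped validation runs at desk scale, chosen to keep the full suite
in the tens of seconds: a 460-gene × 100-sample compendium for recovery
(the published analysis used ~19,500 genes × 8,555 samples; the statistical
machinery is size-independent), 1000 target randomizations on a 300-gene ×
40-sample noise matrix for null calibration, 100 random instances per
oracle-equivalence check, and 50 simulation seeds for the guard-contrast
exclusion rate. The published headline counts (38 TFs, 1145 targets, 1511
edges, and the cohort-level validation rates) depend on the full GTEX /
TCGA / GEO downloads and are out of scope here; the published Bonferroni per-test
level 0.05/(1313·18165) ≈ 2e-9 is reproduced analytically.

## Known limitations

* Activity scores are regression t-statistics: scale-free within a sample
  and convex in the underlying alignment, so they compress or amplify
  nonlinearly at strong signal; compare them across samples, not across
  datasets or against the latent activity scale.
* When several regulons are co-active in a sample and together dominate the
  network gene set, the common elevation is absorbed by the intercept and
  each TF's score reflects its activity *relative to the other active
  TFs* — with many TFs (as in the published 38-TF network) the effect is
  diluted, but with very few it is visible.
* The univariate regression inherits any target mis-assignment from the
  build; the partial-correlation step needs the compendium to contain
  samples that decorrelate rival TFs.
* The moderated t assumes approximately normal log-expression within
  groups; the rank-sum option is provided as the distribution-free check.
* DNAm mode presumes promoter-centric, anti-correlated regulation;
  enhancer-mediated regulation is not modeled.
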