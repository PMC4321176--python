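# methmatch

Analysis pipeline for **matched two-tissue DNA methylation studies**: given
beta-value matrices for the same subjects measured in two accessible tissues
(e.g. buccal epithelial cells and peripheral blood mononuclear cells), it
quantifies how much methylation differs *between tissues*, how
inter-individual *variability* differs between tissues, and how each
tissue's methylation associates with demographic factors. It is aimed at
population-epigenetics researchers deciding which surrogate tissue suits an
epigenome-wide association study.

## What it computes

For a matched cohort of *n* subjects x 2 tissues over ~1,000 promoter CpGs
(beta values β ∈ [0, 1]):

- **Quality control** — removes probes overlapping SNPs, on sex chromosomes,
  with polymorphic CpGs, with β = 0 in more than *n* − 2 subjects, or failing
  background detection (detection p > 0.05) in more than 3 subjects; remaining
  zeros are replaced by the tissue-wide minimum positive β.
- **Tissue specificity** — probe-wise paired t-tests with
  Benjamini–Hochberg correction; Δβ = mean β(B) − mean β(A);
  *tissue-specific* probes have adjusted p < 0.001 and |Δβ| > 0.2
  (*highly* tissue-specific: |Δβ| > 0.4); methylation categories
  (hypo < 20%, heterogeneous 20–80%, hyper > 80%); one-way intraclass
  correlation ICC = (MS_between-subjects − MS_within-subjects) /
  (MS_between-subjects + MS_within-subjects), which approaches −1 when
  tissues differ more than individuals; sample-wise Pearson correlations
  within and between tissues, stratified by CpG-island density class
  (HC / IC / LC, derived from GC content, observed/expected CpG ratio and
  island length); an exact Wilcoxon signed-rank test on subject mean betas.
- **Differential variability** — per-probe β range and SD per tissue;
  Levene/Brown–Forsythe tests of equal variance on M-values
  (log2 β/(1 − β)) with BH correction; a ±20% variance-concordance band;
  probe-wise cross-tissue Pearson correlation with Storey q-values.
- **CpG-density enrichment** — one-tailed hypergeometric tests of any probe
  subset against the analyzed population per density class, with the upper
  tail P(X > k) for enrichment and the lower tail P(X ≤ k) for depletion
  (the two tails are exact complements).
- **Demographic associations** — per tissue and variable: Wilcoxon rank-sum
  (sex, ethnicity) or Pearson correlation (age, BMI, alcohol), Storey
  q-value FDR with smoother-based π₀ estimation, and p-value-distribution
  diagnostics (left skew indicates likely association).
- **Synthetic cohorts** — a generator that emulates this study design
  (bimodal methylation with class-dependent levels, LC-concentrated tissue
  differences, tissue-discordant variance, planted demographic effects, QC
  artifact probes) together with a per-probe truth table, so every stage has
  parameter-recovery tests.

## Worked example

Run the numbered drivers in `analysis/` (each writes tables under
`results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quality_control.py
python analysis/03_tissue_specificity.py
```

Output of the quality-control and tissue-specificity steps on the default
synthetic cohort (25 subjects, seed 1):

```
input probes: 1053
  removed  20 for snp_overlap
  removed  15 for sex_chromosome
  removed  10 for polymorphic_cpg
  removed   5 for zero_prevalence
  removed   5 for detection_failure
retained: 998 probes, 25 subjects
361 probes (36.2%) differ at adjusted p < 0.001
174 tissue-specific (17.4%), 97 highly tissue-specific (9.7%)
mean correlation within A 0.972, within B 0.973, between 0.842
between-tissue correlation by CpG class: {'HC': 0.846, 'IC': 0.809, 'LC': 0.788, 'uncategorized': 0.866}
global tissue shift: signed-rank p = 5.96e-08, 25/25 subjects higher in tissue B
```

Reading this: after QC the cohort matches the intended 998-probe universe;
about a third of probes differ significantly between tissues and 17.4% pass
the additional |Δβ| > 0.2 effect-size filter; samples correlate much more
strongly within a tissue than across tissues; the low-CpG-density (LC) class
shows the weakest cross-tissue agreement; and every subject's blood-like
tissue is globally more methylated than their buccal-like tissue (exact
signed-rank p ≈ 6e-8, the smallest value attainable at n = 25). Subsequent
drivers (`04`–`07`) add the variability/concordance analysis, density
enrichment of the variable loci (LC-enriched: p = 1.3e-7 in tissue A,
p = 6.6e-3 in tissue B on this cohort), the demographic scans (45 of the 50
planted sex-associated probes recovered at q ≤ 0.05 in tissue B, none called
in the null tissue A), and a consolidated run summary with truth-recovery
metrics.

The same pipeline runs on real data: `methmatch qc|run|enrich|assoc --help`
describes the file-based CLI (tab-separated beta matrices, sample sheet,
probe annotation).

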