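# cgimeth

Analysis of the interplay between promoter CpG-island methylation and gene
expression in matched normal/tumor cohorts, for computational epigenomics
work on array-style methylation data (probe-level beta values) with paired
RNA-seq expression, segmented copy number and clinical follow-up.

A promoter locus is modeled as the CpG island plus its shores (≤2 kb) and
shelves (2–4 kb) — "CGI+SS".  The package provides four linked analyses and
a synthetic-cohort generator with a full ground-truth record:

1. **Signature clustering.** Each locus's *signature* is the vector of
   per-probe mean beta values ordered by position.  Signatures of different
   lengths are compared with a partial-boundary dynamic-time-warping
   distance,

       DTW(s₁, s₂) = min over admissible paths w of Σₖ (y¹_{w₁ₖ} − y²_{w₂ₖ})²,

   where paths start anywhere on the first row/column of the alignment grid
   and end anywhere on the last row/column.  Ward clustering on the
   dissimilarity matrix, with bootstrap subsampling (Fowlkes–Mallows
   concordance) to select the number of clusters, separates hypo-methylated
   (cluster 1), hyper-methylated (cluster 2) and cancer-specific
   hemi-methylated (cluster 3) loci; cluster 3 splits into "3up"/"3down" by
   the matched normal-tissue label.
2. **CIMP survival stratification.** Tumors are clustered on their mean
   methylation over 3up loci into low/intermediate/high strata and assessed
   by Kaplan–Meier/log-rank and a multivariate Cox model (stratum, combined
   ER/HER2 factor, nodal status, age, tumor size).
3. **Predictive R².** Per gene, the squared Pearson correlation between
   held-out expression and cross-validated predictions (3-fold CV, repeated)
   under several models: least squares on the locus mean beta, lasso/ridge
   on the full probe profile (penalty by nested 3-fold CV), least squares on
   copy number, and a combined lasso.  Probewise correlations are pooled by
   strand-oriented region; transcription-factor enrichment of top genes uses
   Fisher's exact test.
4. **Copy-number integration.** Gene-level log ratios from SEG segments at
   the TSS, marginal and joint predictive power, and the independence of
   methylation- vs CNV-based predictability.

## Worked example

```python
import cgimeth as cg

cohort = cg.simulate_cohort(cg.SimConfig(seed=7))          # matched cohort + truth
profiles = cg.build_profiles(cohort.beta_cancer, cohort.manifest.probes,
                             annotation=cohort.manifest.genes,
                             islands=cohort.manifest.islands)
sigs = [cg.mean_signature(p, condition="cancer") for p in profiles]
D = cg.dissimilarity_matrix(sigs)
assignment = cg.ward_cluster(D, k=3, cgi_ids=[p.cgi_id for p in profiles])
print(len(profiles), sorted(set(assignment.labels.values())))
```

prints `70 [1, 2, 3]`: of 100 simulated loci, 70 pass the ≥20-probe filter,
and the Ward cut at k=3 yields the three methylation classes (with island
means supplied, labels are canonical: 1 = hypo-, 2 = hyper-, 3 =
hemi-methylated).  Scoring one regulated gene:

```python
import numpy as np
gene, (probes, w) = next(iter(cohort.truth.regulated_genes.items()))
prof = {p.cgi_id: p for p in profiles}[
    cohort.manifest.genes.set_index("gene_id").loc[gene, "cgi_ids"].split(";")[0]]
res = cg.predictive_r2(cohort.expr_cancer.loc[gene].to_numpy(),
                       prof.betas.to_numpy().T, model="lasso_full",
                       cv_repeats=20, seed=0)
print(round(res.score, 2))
```

prints `0.32`: about a third of this gene's expression variance is explained
out-of-sample by its promoter methylation profile, the range seen for the
strongest methylation-associated genes in tumor cohorts.

The same stages run from the shell:

```bash
cgimeth simulate --out sim --seed 7
cgimeth build-profiles --betas sim/beta_cancer.tsv --manifest sim/manifest.tsv \
    --islands sim/islands.bed --annotation sim/annotation.tsv --out prof
cgimeth cluster --signatures prof/signatures.tsv --k auto --out clust
cgimeth run-all --out run1 --seed 7      # full pipeline from one master seed
```

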