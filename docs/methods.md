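# Methods

`cgimeth` analyzes the interplay between promoter CpG-island methylation and
gene expression in matched normal/tumor cohorts.  A promoter locus is the
CpG island (CGI) together with its shores (up to 2 kb from the island edge)
and shelves (2–4 kb), abbreviated CGI+SS.  The package implements four
linked analyses — shape-based clustering of methylation signatures,
CIMP-style patient stratification with survival models, cross-validated
prediction of expression from probe-level methylation, and integration with
segmented copy number — plus a synthetic-cohort generator that plants the
structures those analyses are designed to recover.

## Signatures and the partial-boundary DTW distance

For each CGI+SS and sample set, the *signature* is the vector
`(X, Y) = ((x_1, y_1), …, (x_n, y_n))` of probe positions and mean beta
values (beta = M/(M+U) ∈ [0,1]), ordered by genomic position.  Only loci
with at least 20 probes are analyzed (`min_probes=20`): fewer probes cannot
resolve within-locus shape.  Probes missing in more than 10% of samples are
dropped; remaining gaps are mean-imputed so every sample contributes a
full-length profile.

Two signatures of lengths m and n are compared by dynamic time warping with
*partial boundary conditions*:

    DTW(s1, s2) = min over paths w of Σ_k (y1[w1_k] − y2[w2_k])²

where a path starts anywhere on the first row or column of the m×n grid,
advances by steps (1,0), (0,1) or (1,1), and ends anywhere on the last row
or column.  Only the beta values enter the cost; positions are used for axis
standardization and region labels, not the alignment.  The dynamic program
initializes every first-row/column cell with its own cost (free start) and
minimizes over the last row and column (free end).  A numba kernel computes
the full dissimilarity matrix; a pure-Python implementation backs the
normalized variant and the fallback path.  Correctness is pinned by a
brute-force enumeration oracle over all admissible paths (tests).

A consequence of opening *both* boundary conditions deserves emphasis:
single-cell paths through the anti-corner cells (first probe of one profile
against the last probe of the other) are admissible, so the distance is
bounded by the squared difference of the profiles' boundary levels, and
near-constant profiles can "slide" along any profile containing their level.
The metric therefore distinguishes classes primarily through their flank
plateau levels and large-scale shape, not fine island structure.  This is a
property of the distance as defined, and the synthetic archetypes (below)
are separable under it because hemi-methylated, hyper-methylated and
normal-like loci genuinely differ across their whole span, flanks included.

Options: `normalize=True` divides by the optimal path length (default off —
the raw sum is the clustering distance); `end_rule="printed"` exposes an
alternative end set `{n}×[1,n] ∪ [1,m]×{n}` for comparison (dimensionally
consistent only when n ≤ m; not used by the pipeline).

## Clustering and canonical labels

Ward agglomeration is run directly on the DTW dissimilarity matrix
(Lance–Williams recurrence via `scipy.cluster.hierarchy.linkage` on the
condensed matrix), not on an embedding.  Because the cut order of a
dendrogram is arbitrary, clusters are relabeled canonically from their
members' mean island methylation: cluster 1 = lowest (hypo-methylated
islands), cluster 2 = highest (fully hyper-methylated), cluster 3, 4, … =
intermediate levels ascending.  This matches the field's usage, in which
the cancer-specific hemi-methylated class is "cluster 3".

The number of clusters is selected by subsampling concordance: per repeat,
two independent 80% subsamples are clustered at each candidate k and the
Fowlkes–Mallows index of the two labelings is computed on the samples they
share; the score is the mean over 100 repeats, and the selected k is the
largest whose score exceeds 0.9 (configurable).  All-identical inputs make
every split arbitrary; that case is flagged degenerate rather than scored.

Cancer cluster 3 is divided into "3up" (hypo-methylated — cluster 1 — in
matched normal tissue) and "3down" (hyper-methylated — cluster 2 — in
normal tissue).  Concordance between conditions is reported as the
contingency table of labels.  Per cluster, the 10 members with the smallest
total within-cluster DTW distance (medoids) summarize the characteristic
shape on a standardized axis: island mapped to [0,1] regardless of width,
flanks in signed kb from the island edge (upstream shore [−2,0), shelf
[−4,−2); downstream shore (1,3], shelf (3,5]), reflected (x → 1−x) for
minus-strand genes so positive flank coordinates are always 3' of the gene.

## CIMP stratification and survival

Each cancer sample is summarized by the vector of its mean beta over every
3up CGI+SS.  Samples are Ward-clustered (Euclidean — these vectors are
positionless means, so DTW would be meaningless) and cut at k=3; strata are
relabeled low / intermediate / high by ascending grand mean.  Prognostic
value is assessed by Kaplan–Meier curves with a k-group log-rank test and a
multivariate Cox proportional-hazards model (lifelines, Efron ties) with
the design: stratum (reference low), combined (ER, HER2) factor (reference
−/−), lymph-node status, age, tumor size.  Events are administratively
censored at 5 years (configurable window).  Binary factor levels whose
carriers have no events cannot be estimated — the partial likelihood drives
their coefficient to −∞ — and are flagged degenerate with a (0, ∞) CI
instead of failing, as are coefficients with |log HR| > 50.  A perfectly
collinear design raises an error naming the columns.  The Cox fit is
cross-checked in tests against a hand-written partial-likelihood oracle.

## Predictive goodness of fit R²

The association between methylation and expression is measured per gene as
the squared Pearson correlation between held-out observations and
cross-validated predictions: per repeat, a random 3-fold split is drawn,
models are fit on training folds and predict the held-out fold, and the
pooled out-of-fold predictions are correlated with the observations; the
score is the mean over repeats (default 100; the test suite and acceptance
script use 20, and 5 for the largest cohort, as a compute/precision
trade-off — the estimator is unbiased in the number of repeats).  Constant
predictions contribute 0; anti-correlated predictions are squared as-is but
counted in a flag, since a squared correlation cannot distinguish them.
This out-of-sample R² is scale-invariant and directly comparable across
genes, unlike mean squared error.

Models: `ols_mean` (least squares on the locus-wide mean beta), `lasso_full`
and `ridge_full` (all probe betas; the penalty is chosen per training fold
by an inner 3-fold grid minimizing MSE over 50 log-spaced values from
λ_max down to λ_max·10⁻⁴, computed by the coordinate-descent path with warm
starts, or a single SVD for ridge), `ols_cnv` (gene-level copy-number log
ratio) and `lasso_combined` (probe betas and the copy-number column,
standardized jointly so the penalty treats them comparably).  Predictors
are standardized on the training fold only.  Genes linked to several
CGI+SS use the one whose island midpoint is closest to the TSS.

For the top-scoring genes, probewise Pearson correlations between beta and
expression are pooled by strand-oriented region (N/S swapped for
minus-strand genes so "S" always means 3') and summarized by median and
quartiles; constant probes are excluded and counted.  Transcription-factor
enrichment of a top-gene list is a one-sided Fisher exact test against a
user-supplied TF list.  Cross-condition concordance of scores is the
squared Pearson correlation over the shared gene universe.

## Copy number

Gene-level copy number is the segmented log2 ratio of the SEG interval
containing the TSS (SEG intervals read as 0-based half-open; a TSS in a
gap is assigned the nearest segment within 1 Mb, else missing and flagged;
overlapping segments over a TSS are an error).  The independence of
methylation- and CNV-based predictive power is summarized by the squared
Pearson correlation between the per-gene `lasso_full` and `ols_cnv` scores.
Note this estimate has a chance floor of ≈ 1/n_genes even under true
independence, so it is computed on cohorts of a few hundred scored genes.

## The synthetic cohort

The generator emulates the data structures the analyses assume.  Defaults
(the study conditions used throughout the tests): 100 CGI+SS on 5
chromosomes, islands 0.6–1.4 kb wide, 10–40 probes per locus placed
uniformly within region tiers (each tier seeded with up to 2 probes so
profiles span island, shores and shelves; the 10–40 range deliberately
leaves some loci under the 20-probe filter), 100 normal and 100 cancer
samples, one gene per CGI with TSS at the strand-matching island edge.

Methylation archetypes are (island, shelf) plateau pairs blended linearly
across the shores: cluster 1 (0.10, 0.80); cluster 2 (0.92, 0.85); 3up loci
follow cluster 1 except in CIMP-member tumors, where they shift to the
hemi-methylated (0.60, 0.55); 3down loci follow cluster 2 in normal tissue
and are partially demethylated to (0.50, 0.73) in all tumors.  Archetype
fractions default to 0.60/0.15/0.15/0.10.  Probe values are Beta-distributed
with mean equal to the class curve and concentration 50 (array-like
precision; shape parameters mean·c and (1−mean)·c, giving bounded support
and tunable bimodality).  The CIMP subgroup covers 30% of tumors; in
addition, every tumor carries one shared N(0, 0.03) offset across all 3up
loci, making the phenotype a continuum — population means at 3up loci are
intermediate while per-sample values are bimodal, and the low/intermediate
split of non-CIMP patients reflects genuine methylation grading rather than
noise.  Without this continuum, Ward at k=3 necessarily splits the CIMP
mode itself (hemi-methylation maximizes the beta variance m(1−m)), which no
parameterization of i.i.d. probe noise can avoid.

Expression is simulated directly on the log2 scale: baseline N(8, 1) — or
N(4.5, 0.5) for genes linked to 3up loci, which are lowly expressed in both
conditions independently of their methylation — minus, for 20 regulated
genes, `effect_size` (3.0) times a positively weighted sum of 3 effect
probes drawn from the strand-oriented effect region (default S_shore,
i.e., the 3' shore), plus a gene-dosage term and N(0, 0.3) noise.  With
these values planted genes reach out-of-sample R² ≈ 0.4–0.5, the range
reported for the strongest methylation-predicted genes in tumor cohorts.
Regulated genes are drawn from cluster-1 loci that pass the 20-probe
filter and have enough oriented effect-region probes.  Copy number is
piecewise-constant per sample and chromosome (3–7 segments, mean 0 with
probability 0.6, else N(0, 0.5)), independent of the methylation truth;
only a `cnv_sensitive_fraction` (0.5) of genes respond to dosage, with
multipliers U(0.5, 1.5) — dosage buffering is what lets methylation- and
CNV-based predictive power vary independently across genes.

Survival is exponential with baseline hazard 0.18/year (≈59% events within
the 5-year administrative censoring window) multiplied by the planted
stratum hazard ratio: low 1.0, intermediate 3.44, high 1.92 — the
intermediate-methylation (CIMP-low-like) group carries the worst prognosis.
Strata are planted as: CIMP members → high; non-members split at their
median 3up methylation into low/intermediate.  ER (70% +), HER2 (20% +),
nodal status (40% +), age N(58, 12) and tumor size N(25, 10) are drawn
independently of survival, so their true hazard ratios are 1.

What the generator does *not* model: probe cross-reactivity, batch effects,
hydroxymethylation, copy-number influence on beta values, intragenic or
long-range CGIs, competing risks, and correlated clinical covariates.
Passing recovery tests therefore demonstrates the pipeline's correctness
and sensitivity under idealized noise, not performance on real arrays.

## Numerical choices and reproducibility

Every stochastic component draws from a `numpy` `SeedSequence` child of one
master seed (generator streams are fixed by name; pipeline stages derive
their seeds the same way), so reruns are bit-identical; tables are written
with a fixed float format to keep outputs byte-stable.  DTW asymmetries
beyond 1e-12 (never observed; the definition is symmetric) would be
symmetrized by averaging.  Ward ties follow scipy's deterministic
nearest-neighbor-chain order.  Lasso paths use tolerance 1e-3 with input
validation disabled on pre-shaped arrays (identical coefficients, ~5×
faster).  Problem sizes in the tests and acceptance script — 100–450 loci,
100–200 samples, 3-fold CV with 5–20 repeats, 100 Cox replicates at
n=2000 — were chosen to keep the full suite in the tens of minutes on one
CPU while leaving every recovery margin wide.

## Known limitations

- The partial-boundary DTW as defined is corner-dominated (see above); a
  windowed or single-sided open-end variant would weight interior shape
  more, but is not what this pipeline specifies.
- Ward on a non-Euclidean, triangle-inequality-violating dissimilarity is a
  heuristic; stability is assessed empirically by the bootstrap.
- The lasso penalty grid is shared across models but selected per training
  fold; very small training folds (n < ~15) make the inner selection noisy.
- `run_all` orchestrates the synthetic pipeline end-to-end; externally
  supplied data are analyzed through the individual CLI stages, which
  accept the same file schemas.
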