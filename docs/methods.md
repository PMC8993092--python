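# Methods

This document records the statistical and numerical choices made in seramir,
at the level of detail needed to reproduce or audit the implementation.

## Study design

The package targets two-group small-RNA count studies with unbalanced,
small-n designs: a handful of patients (default 8) against a larger control
pool (default 22), sequenced to library depths of roughly 1–5 million mapped
small-RNA reads. Group labels are `patient` and `control` throughout.

## Filtering

Before any normalization, miRNAs are kept if their counts-per-million (CPM,
computed against *raw* library sizes) reach at least 1 in at least 2
libraries. Filtering on raw library sizes keeps the filter independent of the
normalization that follows.

## TMM normalization

Between-sample normalization uses the trimmed mean of M-values:

- The reference sample is the one whose upper-quartile CPM is closest to the
  mean upper-quartile CPM across samples.
- For each sample vs the reference, genes with zero counts in either sample
  are dropped; M-values (log₂ ratio of CPM proportions) are trimmed by 30 %
  on each side, A-values (average log₂ abundance) by 5 % on each side.
- The factor is the weighted mean of the surviving M-values with
  precision weights 1/var(M) ≈ [(N₁−y₁)/(N₁y₁) + (N₂−y₂)/(N₂y₂)]⁻¹,
  exponentiated base 2.
- Factors are recentred so their geometric mean is 1; the centering constant
  is retained so a held-out sample can later be scaled consistently against a
  training-set reference (see nested cross-validation below).

Effective library sizes are raw library sizes × factors and enter the GLM as
offsets.

## Negative-binomial quasi-likelihood F-test

Each miRNA is modelled as NB(μ, φ) with var = μ + φμ² and a log-linear mean,
log μᵢⱼ = βᵢ₀ + βᵢ₁·1[j ∈ patient] + log Ñⱼ, fitted by IRLS (vectorized
across miRNAs; the two-group design admits a closed-form 2×2 solve, and step
sizes are clipped for stability).

Dispersion estimation uses the Cox–Reid adjusted profile likelihood
APL(φ) = ℓ(β̂(φ), φ) − ½ log det(XᵀWX), evaluated on a fixed 41-point
logarithmic grid from 1e-5 to 16 with quadratic interpolation of the argmax:

- **Common** dispersion maximizes the APL summed over all miRNAs.
- **Trended** dispersion: miRNAs are binned into 20 equal-occupancy bins by
  average log-CPM, a per-bin common dispersion is computed, smoothed by a
  window-3 moving average, and interpolated back onto each miRNA's
  average log-CPM.
- **Tagwise** dispersion shrinks the per-miRNA APL maximizer toward the trend
  with weight prior_df/(df + prior_df) (prior_df = 10 by default):
  φ_tag = φ_trend + (φ_raw − φ_trend)·df/(df + prior_df). This is a moment
  form of the weighted-likelihood shrinkage; it preserves the defining
  invariants (tagwise → raw as prior_df → 0, tagwise → trend as
  prior_df → ∞) and agrees closely with edgeR in practice.

Quasi-likelihood dispersions are raw deviance/df_residual values (df reduced
for groups that are all zero), squeezed by empirical Bayes: the raw values
are assumed scaled-F distributed, the prior df and location are estimated by
moment matching on log-values (Newton inversion of the trigamma function),
and posterior values are df-weighted averages of raw and prior — the
standard limma `fitFDist`/`squeezeVar` construction, reimplemented.

The test statistic is F = (deviance under null − deviance under full) / s²_post
with p-values from F(1, df_residual + df_prior), falling back to χ²₁ when the
prior df is infinite. Multiple testing uses Benjamini–Hochberg. Reported
log₂ fold changes come from a refit on counts augmented by a prior count of
0.125 (scaled by library size), which stabilizes estimates at low counts.

A miRNA is called significant at the default thresholds p < 0.05 and
|log₂FC| > 1 (both configurable); `summarize_de` reports counts, directions
and the one-decimal percentage, rounded half away from zero.

### Calibration evidence

On 2,000 simulated null miRNAs (8 vs 22, φ = 0.2) the raw-p rejection rate at
α = 0.05 is 0.0505 — inside a 3-standard-error binomial band. A known common
dispersion of 0.4 (60 samples) is recovered as 0.405; Poisson data drives the
estimate to the grid floor (1e-5). During development the pipeline was also
cross-checked against an independent reference implementation of the same
model family: identical TMM factors, log₂FC correlation 1.0, −log₁₀ p
correlation > 0.999, and identical significance calls on a shared dataset.
That cross-check used an R toolchain and is not part of the test suite; the
suite relies only on self-contained oracles.

## Nested leave-one-out cross-validation

For each held-out sample:

1. The full DE pipeline (filter → TMM → dispersions → QL F-test) is rerun on
   the training samples only, and miRNAs are ranked by p-value (ties broken
   by |log₂FC|, then ID).
2. The top-k miRNAs become the fold's panel. Features are
   log₂(CPM + 0.5) with CPM computed against training effective library
   sizes; the held-out sample's factor is computed against the training
   reference and divided by the training centering constant.
3. Features are standardized by training means and SDs (ddof = 1; zero SDs
   replaced by 1) and an RBF SVM (C = 1, γ = 1/k) is fitted.
4. The held-out sample's decision score is recorded, oriented so larger
   means more patient-like.

Accuracy, sensitivity, specificity and MCC come from the pooled confusion
matrix (MCC defined as 0 when any marginal is empty). AUC is the
Mann–Whitney statistic over pooled held-out scores, counting ties as ½; ROC
points are emitted per distinct threshold.

Per-fold DE rankings are computed once and cached across panel sizes, so the
size sweep costs one DE run per fold regardless of how many sizes are tried.

**Saturation sweep.** Panel size starts at 6 and increases by 1. The sweep
stops when accuracy has failed to improve for `patience = 3` consecutive
sizes (or at `max_size`); the optimal size is the smallest size attaining the
best accuracy. The pooled panel is the union of the per-fold selections at
the optimal size.

**Pooled-AUC bias on null data.** Because decision-score scales differ
between folds, pooling held-out scores yields a *pessimistic* AUC under the
null — individual seeds can fall well below 0.5 (values near 0.2 have been
observed) even though accuracy sits at chance. This is expected behaviour of
pooled-score LOOCV AUC, not a defect; accuracy and MCC are the primary null
diagnostics.

**Leakage sentinel.** The test suite includes a deliberately leaky variant
that selects features on the whole dataset before LOOCV. On null data the
honest in-fold pipeline must score at least 0.05 lower in mean accuracy over
five seeds; the observed gap during development was ≈ 0.19 (0.67 vs 0.87),
and the margin of 0.05 was fixed before the final test run.

## Target aggregation

Per-database edge lists carry kappa-style confidence scores in [0, 1].
Edges at or above the per-database threshold (default 0.6) are kept;
duplicate (miRNA, gene) rows within a database keep the maximum score.
Support is the number of distinct databases backing a pair; pairs are ranked
by (support desc, max score desc, gene ID asc) and capped at 50 genes per
miRNA. Cross-disease target sets are partitioned into Venn cells keyed by
the exact subset of diseases containing each gene (cells are disjoint and
cover the union, which the suite verifies on random sets).

## Enrichment

For each term, the overlap k between the study set and the term's annotated
genes is tested against a hypergeometric null over the population. The
two-sided p-value doubles the smaller tail, capped at 1:
p = min(1, 2·min(P[X ≥ k], P[X ≤ k])). An optional binomial approximation is
available for large populations. Family-wise error is controlled by Holm's
step-down Bonferroni procedure. Terms are assigned ontology levels by
shortest path from the root set (nodes of in-degree 0) and filtered to
levels 4–16 by default, which removes both uselessly broad and uselessly
narrow terms.

## Synthetic data generator

Counts are NB draws with var = μ + φμ². Baseline log-mean relative
abundances are uniform on ±2.5 (natural log scale) and normalized to
proportions per condition; library sizes are uniform on [1e6, 5e6]. A
fraction `frac_de` of miRNAs receives a log₂ fold change of ±`lfc_magnitude`
with fair-coin signs (patients relative to controls). Optional tagwise
dispersion variation adds lognormal noise around the common φ. All draws
come from one `numpy.random.default_rng(seed)` stream with a fixed,
documented order, so every artifact is reproducible from the seed alone.

The generator intends to emulate the *statistical* structure of serum
small-RNA-seq (overdispersion, depth variation, sparse planted signal); it
does not model hemolysis artifacts, batch effects, compositional distortion
from a few dominant miRNAs, or isomiR structure.

## Third-party components

Standard numerics are delegated rather than reimplemented: BH and Holm
corrections to `statsmodels.stats.multitest`, the SVM and PCA to
scikit-learn, distribution functions and rank statistics to SciPy, and
ontology traversal to NetworkX — each behind a package-level function with
an independent brute-force oracle in the test suite. The NB/TMM/QL machinery
itself is original code, since its exact conventions (trim fractions,
CR adjustment, squeezing) are the point of the package.

## Limitations

- The GLM supports the two-group design only; covariates (age, sex,
  hemolysis score) are not modelled.
- Tagwise dispersion uses moment shrinkage rather than full
  weighted-likelihood maximization (see above).
- Pooled-score LOOCV AUC is biased pessimistic under the null.
- Enrichment treats annotations as flat sets; no propagation of gene
  annotations up the ontology is performed beyond level assignment.
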