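# Methods

`pdac-cfmethyl` implements a cfDNA multi-analyte diagnostic analysis for
pancreatic ductal adenocarcinoma (PDAC): differentially methylated region
(DMR) discovery from paired tumor/NAT bisulfite counts, plasma region
methylation quantification, a three-step marker-selection cascade, white
blood cell (WBC)-filtered mutation features, random-forest classification
and CA19-9 OR-rule integration — exercised end-to-end on a synthetic
cohort generator. This note records the models, defaults, and design
choices, and what the synthetic experiments do and do not demonstrate.

## DMR discovery model

Per-sample methylation at CpG *i* is modeled beta-binomially:
`m_i ~ BetaBin(n_i, mu_i, phi_i)` with variance
`n mu (1-mu) (1 + (n-1) phi)`; `phi` is the intra-class correlation form
of the overdispersion, so `phi -> 0` recovers the binomial.

**Smoothing.** Each sample's proportions are smoothed by a coverage-
weighted flat kernel: the smoothed value at a CpG is
`sum(m_j)/sum(n_j)` over CpGs within ±100 bp (window 200 bp). The window
was set so that a DMR of typical size (~200–500 bp; the discovery
literature reports a median near 200 bp) is not diluted below the
region-level effect threshold: with a flat kernel, the smoothed
difference at the center of a DMR of length L is roughly
`effect * min(1, L/window)`, so a 500 bp window would halve a 200 bp
DMR's apparent effect and make the >0.2 rule uncallable at realistic
effect sizes. A 200 bp window still pools ~7 CpGs x all pairs at the
default spacing.

**Dispersion.** `phi_i` is estimated per CpG by the chi-square method of
moments within each group, combined across groups by degrees of freedom,
and shrunk toward the genome-wide df-weighted mean with a prior weight of
20 pseudo-replicates (empirical Bayes); estimates are clipped to
[1e-6, 0.99]. An infinite prior weight collapses every CpG to the global
mean — the shrinkage limit used as a sanity check in tests.

**Paired test.** For each pair k the smoothed proportions are mapped to
the variance-stabilizing arcsine-square-root scale `g = arcsin(sqrt(p))`,
on which the model variance `Var(g) = sum n_j (1+(n_j-1) phi_j) / (4 N^2)`
is free of `p`. This matters at near-0/near-1 methylation, where the
proportion-scale normal approximation both miscalibrates and loses power
(an all-zero count group has an estimated proportion variance of zero).
The per-CpG statistic is the inverse-variance-weighted mean of per-pair
g-differences over its standard error, referred to N(0,1), two-sided.
Reported `diff` (and the per-CpG |diff| > 0.1 rule) stay on the
proportion scale; the reported `se` is the delta-method proportion-scale
equivalent, so `z` is computed on the g-scale rather than literally
`diff/se`. Against a brute-force beta-binomial likelihood-ratio oracle
(grid search over means), accept/reject decisions at alpha = 0.05 agree
on >99% of random small-count instances.

A CpG is *differentially methylated* (DM) when `p < 0.05` and
`|diff| > 0.1`. These per-CpG thresholds are package choices: the region
rules below need a definition of a DM CpG, and none is standard.
CpGs covered in fewer than 10 pairs are excluded and counted in the QC
report.

**Region assembly.** Candidates are maximal runs of same-direction DM
CpGs in which consecutive DM CpGs lie ≤ 500 bp apart; a candidate spans
first to last DM CpG, and its members are all tested CpGs in the span. A
candidate is emitted iff it passes all four rules: |mean smoothed
difference| > 0.2 (signed, in the run's direction), length ≥ 50 bp,
≥ 3 CpGs, and ≥ 80% member CpGs DM. Only maximal runs are evaluated, so
output regions never overlap. The mean difference uses smoothed values,
consistent with the model that declared the CpGs DM. The assembly is
verified exactly against an O(n²) window-enumeration oracle.

## Plasma quantification and marker selection

Region methylation per plasma sample is `sum(m)/sum(n)` over covered
member CpGs; uncovered regions are missing and are median-imputed from
training rows only, inside the selection/training stage, never at
quantification time.

The cascade:

1. **All-relevant selection (shadow features).** Per iteration, every
   feature is duplicated as a within-column permutation; a random forest
   is fit on the augmented matrix; a real feature scores a *hit* when its
   impurity importance beats the best shadow importance. After `max_iter`
   (default 50) iterations, features are accepted/rejected by one-sided
   binomial(n, 1/2) tests at alpha = 0.05 with Holm step-down across
   features; unresolved features are settled by comparing their median
   importance to the median of per-iteration shadow maxima (so no feature
   is left undecided).
2. **Minimal-optimal reduction (RFE).** Forest-importance-ranked
   elimination down a geometric size grid; at each size a stratified
   cross-validated AUC (default 5 folds); the chosen size is the smallest
   whose CV AUC is within one standard error of the curve maximum. The
   one-SE rule is a package choice — the size criterion used in the
   original analyses of this kind is typically unstated.
3. **Tissue-plasma concordance.** Keep only markers that are
   tissue-hypermethylated AND plasma-elevated in cases: PDAC median >
   healthy median and one-sided Wilcoxon rank-sum p < 0.05. Tissue-hypo
   markers are dropped regardless of plasma behavior (their plasma signal
   is often stroma-driven and, in the generator, frequently *elevated*
   in cancer plasma despite tissue hypomethylation — the discordance
   phenomenon). Markers missing in >50% of plasma samples are excluded.

The stages are nested by construction (final ⊆ stage2 ⊆ stage1) and all
selection runs on training rows only.

## Mutation features

cfDNA variants shared with the same individual's WBC sample (exact allele
identity) are removed as clonal hematopiesis; the shared set feeds a
Pearson concordance report of cfDNA vs WBC allele fractions. Hotspots
collapse protein changes to residues (G12D, G12V → G12) and require ≥ 3
distinct patients (recurrence threshold; the residue collapsing mirrors
"KRAS p.G12"-style reporting). Binary feature matrices (top-10 genes by
distinct patients — switchable to variant counts —, KRAS/TP53 only, or
top-10 hotspots) are frozen on training samples; only non-synonymous
variants contribute.

## Classification and integration

Random forest (500 trees, sqrt(p) features per split, unlimited depth;
scikit-learn) trained with stratified 10-fold CV; the CV AUC is computed
on pooled out-of-fold scores and the deployed model is refit on all
training rows. The decision threshold is the smallest cut achieving the
target specificity (default 0.95) on the *training out-of-fold scores*,
placed at the midpoint of the bracketing observed scores, and frozen
before any test-set evaluation. Bi-omics variants concatenate the binary
mutation features to the methylation matrix and are trained and
evaluated as separate models; the primary model is methylation-only.

CA19-9 integration is the OR-rule: positive iff the methylation model is
positive OR CA19-9 > 37.0 U/mL (strict; missing CA19-9 reduces to the
methylation call). A joint trained model is deliberately not offered: the
motivating study design lacks CA19-9 for training controls, making the
OR-rule the only defensible integration.

## Evaluation

AUC is the Mann-Whitney pairwise concordance (ties count 1/2), computed
via midranks, hence exactly `U/(n1*n0)` of the rank-sum statistic on the
same data. Bootstrap CIs are percentile, resampled within class (default
2000 draws; 1000 in pipeline reports). Rank-sum tests are exact (scipy)
when min(n) ≤ 8 without ties, otherwise normal with tie correction.
Stage-stratified sensitivity merges stage 0 into stage I (stage-0 cases
are rare; switchable). The rescue analysis counts methylation-positive
calls among CA19-9-negative (≤ 37.0) cases.

## Synthetic cohort generator

What it emulates, with defaults:

- **Landscape**: 100k CpGs over 5 chromosomes, geometric spacing with
  mean 30 bp (a CpG-dense targeted panel; the full 5.6M-site panel of the
  motivating assay is scaled down for desk-scale runs).
- **Tissue**: 32 tumor/NAT pairs, Poisson(30) coverage, beta-binomial
  dispersion 0.1. Baselines are block-bimodal (CGI-like low, open-sea-like
  high). 50 hyper + 60 hypo DMRs (the ~538:635 hyper:hypo ratio of the
  motivating study at a density compatible with 100k CpGs), length
  200–500 bp, effect ±0.3, ≥ 2 kb apart.
- **Plasma**: 255 PDAC / 209 healthy; per-CpG mean is the mixture
  `(1-f)*baseline + f*tumor_plasma`; Poisson(150) coverage and region-level
  dispersion 0.003 (deep targeted cfDNA sequencing; tight healthy
  baselines are what makes few-marker plasma classifiers plausible at
  percent-level tumor fractions). Hypo-DMRs are plasma-discordant with
  probability 0.7 ("the majority"): their tumor-derived plasma signal is
  elevated, not depressed.
- **Tumor fraction**: log-scale range (0.01, 0.2), stage-banded: stage
  band b (0/I, II, III, IV) confines f to the b-th quarter of the log
  range, making f stochastically increasing with stage. The lower bound
  is set so the stage-I band straddles the methylation model's detection
  threshold — a 0.001 lower bound would make stage I/II undetectable at
  any plausible coverage, contradicting the observed stage-I performance
  of assays of this class and erasing the stage gradient the map exists
  to reproduce.
- **Variants**: per-gene tumor driver probabilities concentrated in
  KRAS/TP53 with hotspot residues (KRAS G12 etc.); tumor variant AF =
  f x U(0.1, 0.6) with a detection floor of 0.03%. CH variants hit 20% of
  individuals, appear in both cfDNA and WBC with lognormal AF noise
  (sigma 0.1, giving Pearson r² ≈ 0.95), plus a 25% background of
  low-AF non-CH variants.
- **CA19-9**: class-conditional lognormal with mu = ln(median) and sigma
  from the IQR ratio of the motivating cohort (PDAC median 149.1, IQR
  39.75–598 → sigma ≈ 2.01; healthy median 7.8, IQR 5.08–11.39 → sigma
  ≈ 0.60). The natural fraction of PDAC draws below the 37 U/mL cutoff is
  ~0.24, matching the reported CA19-9-negative subgroup without forcing;
  an optional parameter pins that fraction exactly.

All draws flow through explicitly passed numpy Generators seeded from
`SimConfig.seed` (one independent stream per generative stage); identical
configs give byte-identical cohorts.

**What passing tests show — and don't.** The generator reproduces the
*statistical structure* the analysis assumes: planted effects, paired
overdispersed counts, mixture-linear plasma signals, stage-linked tumor
fractions, CH contamination with matched AFs, and class-separated CA19-9.
It does not emulate real-data complications: batch and GC effects,
fragment-length biases, incomplete bisulfite conversion, correlated
dispersion along the genome, copy-number distortion of AFs, or benign
pancreatic conditions that elevate CA19-9. Recovery/selection results on
synthetic cohorts therefore validate the implementation and the method's
internal logic, not clinical performance; absolute sensitivities
(e.g. stage-I) on synthetic data are not calibrated to any cohort.

## Pipeline, sizes and numerical choices

`run_full` derives every stage seed from the master seed by SHA-256, so
runs are reproducible end-to-end and stages are independently seeded.
The default split is 70/30 stratified by group; a cohort-pinning mode
reproduces designs where whole control cohorts are assigned to one split.
Integration-scale runs in the test suite and acceptance script use
scaled-down cohorts (15k–20k CpGs, 16 pairs, 12+12 planted DMRs,
450/250 plasma samples) chosen so each stage band retains n ≈ 20–45 test
cases and binomial noise does not mask the structural properties being
checked.

Degenerate inputs: zero-coverage CpGs propagate as missing and never
crash region ratios; single-class training labels raise; unachievable
specificity targets warn and place the threshold above all scores; empty
variant tables skip the mutation arm with a warning rather than failing
the run.

## Known limitations

- When candidate markers are statistically exchangeable — e.g. plasma
  signals that are pure tumor-fraction mixtures with identical effect
  sizes — the minimal-optimal RFE stage correctly reports that a small
  subset suffices and prunes the redundant twins (the CV-AUC curve is
  flat within one SE down to ~3 such markers). The cascade is therefore
  not a tool for recovering *every* planted signal under perfect
  redundancy; it recovers the all-relevant set at stage 1 (the shadow
  feature stage, which does keep redundant copies by design) and a
  sufficient predictive subset at stage 2. On heterogeneous cohorts the
  two stages differ far less.

- The per-CpG DM definition (p < 0.05, |diff| > 0.1) and the merge gap
  (500 bp) are conventions; DMR counts respond to them, as the
  criteria-relaxation tests document.
- The hierarchical model is an empirical-Bayes reading; a full Bayesian
  smoothing model with locally adaptive bandwidth could differ at
  coverage boundaries.
- Forest importances (impurity-based) are biased toward high-cardinality
  features; with all-continuous methylation ratios plus binary mutation
  flags this mildly favors the continuous features in selection.
- The exact rank-sum path is limited to min(n) ≤ 8 without ties;
  mid-size exact p-values fall back to the tie-corrected normal
  approximation (within 0.01 of exact at n=12/12 in tests).
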