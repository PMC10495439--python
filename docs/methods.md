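# Methods

## The problem and the model

PD-L1 expression is the most widely used biomarker for selecting patients
for immune checkpoint inhibitors (ICI), yet its predictive value varies
sharply between — and within — cancer types.  `predscreen` implements a
pipeline for quantifying that predictive value, finding transcriptomic
modulators of it, and evaluating biomarker-stratified efficacy inside the
resulting patient subsets.

### Predictiveness as a hazard-ratio difference

For one cancer type, let HR₊ and HR₋ be the pooled hazard ratios (ICI vs
standard-of-care; HR < 1 favors ICI) in the biomarker-positive and
biomarker-negative trial subgroups.  Since 1 − HR measures the reduction
in risk, the biomarker's predictiveness is summarized as

    HRD = (1 − HR₊) − (1 − HR₋) = HR₋ − HR₊ ,

computed on the hazard-ratio scale even though pooling happens on the log
scale.  A positive HRD means biomarker-positive patients gain more from
ICI.  Subgroups are pooled with the DerSimonian–Laird random-effects
estimator (fixed weights 1/se², Q, τ² = max(0, (Q−(k−1))/(Σw−Σw²/Σw)),
random weights 1/(se²+τ²)); heterogeneity is reported as
I² = max(0, (Q−(k−1))/Q)·100.  Standard errors of published hazard ratios
are back-calculated from their 95% CIs using the exact normal quantile
1.959964, not the rounded 1.96.  The source publications do not state how
the interaction p-value was obtained; we use the standard fixed-effect
subgroup-difference test, z = (y₊−y₋)/√(se₊²+se₋²), and document that as
an assumption, not a claim of fidelity.  Trials were excluded in the
original analyses for "substantial heterogeneity" without a numeric rule;
we expose an I² flag (default threshold 75%) and leave exclusion to the
caller.

### Modulator screen

Step 1 correlates per-cancer median expression of each candidate gene
(reference-atlas panel, log2(TPM+0.001) scale) with HRD across cancers,
separately for OS and PFS (Spearman, midrank ties).  Genes with
unadjusted p < 0.05 for **both** endpoints pass.  No multiplicity
adjustment is applied, matching the screening design this reproduces;
Benjamini–Hochberg q-values are emitted for reference only.

Step 2 ranks the survivors within a single treatment arm by the Cox model

    hazard = exp(a·B + b·V + d·B·V) · h₀(t)

with B the biomarker indicator and V the candidate, both dichotomized at
the in-arm median (value ≥ median → 1; the continuous alternative exists
behind a flag but is off by default).  Candidates are ordered by the Wald
z = d/se(d); positive d means high V erodes the biomarker's favorable
association.  Ties on z break lexicographically by gene id;
non-convergent fits (including separation) are flagged `estimable=False`
and ranked last.

### Predictiveness score and PH/PL split

The top modulator's per-cancer medians are regressed on OS HRD by
ordinary least squares, giving PS = slope·V + intercept.  Leave-one-out
cross-validation (explicit n refits) provides an out-of-sample RMSE as a
diagnostic only — the deployed model is the all-points fit.  Patients are
scored from their own expression and split at the median score of a
reference population: the ICI arm for single-arm analyses, all patients
(ITT) for arm comparisons, mirroring the two conventions trial analyses
use.  Score ≥ median defines Predictiveness-High (PH); with the
empirically negative slope, PH corresponds to *low* modulator expression,
an orientation asserted in the tests.

### Stratified efficacy

Within PH, PL, and ALL, patients are stratified by PD-L1: IHC percent at
1% (or 5%), three levels [0,1), [1,50), [50,100] (published wording
"1–50% and ≥50%" overlaps at 50; we fix 50 in the upper bin), or RNA
expression at the reference-population median or 25th/75th percentiles.
Survival comparisons report a univariate Cox HR (Efron ties) with 95% CI
plus a log-rank p; response comparisons report ORRs with Clopper–Pearson
intervals and a two-sided Fisher exact p (minimum-likelihood convention).
Non-evaluable patients count as non-responders (intention-to-treat
denominators; an evaluable-only flag exists).  Degenerate cells are
emitted with `estimable=False` so grids stay rectangular.  Robustness
splits rerun the grid within TMB (≥ 16 mut/Mb is high), TNB (≥ median),
or immune-subtype levels.

### TME profiling

Expression is quantile-normalized (columns forced onto the rank-mean
reference distribution, midrank averaging for ties) and gene-centered.
Signature scores are unweighted means over the present genes of a set
(CD8 score = mean of CD8A, CD8B), with per-signature coverage recorded.
Pathway-enrichment scoring (GSVA-style) is deliberately replaced by this
mean-signature hook — an explicit fidelity reduction; an external
enrichment engine can be plugged in at the same interface.  Immune
subtypes come from resampled consensus clustering of externally supplied
cell fractions (deconvolution is out of scope): per repetition, subsample
80% of samples, cluster hierarchically, cut at k = 2..6; the consensus
entry of a pair is its co-clustering rate among co-sampled repetitions;
final labels cluster 1 − consensus; k is chosen by the largest k whose
relative delta-area under the consensus CDF exceeds 0.1.  Defaults are
1000 repetitions, pItem 0.8, pFeature 1.  The general engine uses
average linkage on 1 − Pearson correlation (the referenced R tool's
default; both configurable).  For cell-fraction tables specifically the
subtype wrapper defaults to Euclidean distance with Ward linkage:
compositional vectors over few cell types make Pearson correlation
ill-conditioned, and average linkage on a compositional continuum chains
into singleton splits.  The "Stromal" summary is Endothelium +
Fibroblasts.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (config, seed) and return a truth
manifest sufficient to recompute every planted quantity.

* **Trial tables** — per cancer, true subgroup HRs are hr_center ∓ HRD/2
  so HR₋ − HR₊ equals the planted HRD exactly; per trial a N(0, τ)
  heterogeneity shift plus sampling noise with se = √(2/events) is added
  on the log scale.  Defaults: 10 cancers with HRDs evenly spaced over
  −0.4..1.0 (the published cross-cancer range), 3 trials per cancer,
  300 patients per arm, τ = 0.05, 70% event fraction.  PFS HRDs are 0.8×
  the OS HRDs, giving the correlated two-endpoint structure the screen
  requires.
* **Expression panels** — the planted modulator's cancer median is the
  score line inverted at that cancer's HRD (default slope −0.76,
  intercept 2.81), with N(0, 0.05) noise on the HRD scale before
  inversion; decoys get the same medians permuted across cancers
  (association destroyed, marginal spread preserved); per-sample values
  add N(0, 0.3) within-cancer noise, 50 samples per cancer, 30 decoys.
* **Cohorts** — 1200 patients randomized 1:1.  Event times are
  exponential (Weibull shape configurable) with rate
  h₀·exp(βT·T + βP·P + βV·V + βPV·P·V + βTP·T·P + βTPV·T·P·V), h₀ = 0.05
  per month, where P and V dichotomize PD-L1 and modulator expression at
  the generating medians.  The *paper-pattern* preset uses
  {T: −0.2, P: +0.1, V: +0.05, PV: 0, TP: −0.5, TPV: +0.8}: the ICI-arm
  biomarker effect is −0.4 + 0.8·V (PH-like patients HR ≈ 0.67, PL-like
  ≈ 1.49; within-arm interaction d = 0.8), the biomarker is essentially
  non-prognostic in the chemotherapy arm, and ICI-over-chemo benefit
  concentrates in biomarker-positive, modulator-low patients.  The *null*
  preset zeroes every coefficient and flattens the HRD gradient.  OS and
  PFS share a gamma frailty (variance 0.1) so endpoint patterns
  correlate; progression is clipped to precede death.  Censoring is
  uniform administrative, with the window solved by root-finding on the
  realized event times to hit the 30% target.  Response is Bernoulli from
  a logistic analogue of the hazard coefficients (baseline ORR ≈ 15%,
  with the same PH/PL divergence); 3% of patients are non-evaluable.
  IHC percent is a noisy logistic transform of PD-L1 gene expression
  (slope 2.5, center 3.5, noise sd 1.0), yielding ≈ 35% of patients below
  the 1% cutoff and a realistic right tail above 50%, so IHC and RNA
  stratification modes exercise the same patients.

What the generator does **not** emulate: read-level RNA-seq counts
(negative-binomial sampling, library-size and batch effects), informative
censoring, non-proportional hazards, correlated decoy genes, missing
data patterns, or multi-site trial structure.  Passing recovery tests
therefore demonstrate that the estimators and the pipeline wiring are
correct under the assumed data-generating model — not that the biological
findings replicate on real trial data, which are controlled-access.

## Numerical choices

* Cox fitting uses a damped Newton iteration on the Efron partial
  likelihood (vectorized over risk sets), stopping at gradient or step
  below 1e-9; standard errors from the inverse observed information.
  Agreement with an independent implementation is asserted to 2e-4,
  which is the latter's own convergence tolerance.  |coef| > 15 on the
  indicator covariates used here is treated as separation and flagged.
* Median survival is the first time with Ŝ(t) ≤ 0.5.
* Spearman p-values use the t-approximation for n ≥ 10 and exact
  permutation enumeration below that.
* Fisher's two-sided p follows the minimum-likelihood convention with
  1e-12 relative slack.
* Dichotomization sends ties at the cutoff to the upper class (≥).
* All tabular outputs are tab-separated UTF-8 with `NA` for missing
  values; every stochastic path draws from a seed recorded in the run
  manifest.

## Problem sizes in the test and acceptance runs

The test suite runs the calibration experiments at the sizes the
pipeline's claims are stated at: 2000 replicates for log-rank uniformity
and Cox type-I error (n = 400 cohorts), 200 seeds for modulator-ranking
and slope recovery and for the PH/PL pattern, 5000 draws for
Clopper–Pearson coverage, and the full enumeration of 2×2 tables with
total ≤ 24.  `scripts/acceptance.py` summarizes the same pipeline over
100 seeds per preset, a size chosen so a complete rerun stays within a
few minutes on one core while keeping Monte-Carlo error on reported
rates near ±5 percentage points.

## Known limitations

* The interaction test for the meta-analysis stage is an assumption (see
  above); alternatives (random-effects meta-regression) are not provided.
* The screen treats cancer types as independent observations; no
  phylogenetic or lineage correlation structure is modeled.
* GSVA-style enrichment, cell deconvolution, TMB/TNB calling and
  single-cell analyses are out of scope; their outputs are inputs here.
* The predictiveness score is single-gene and unregularized by design.
* Consensus clustering recomputes full pairwise distances per
  repetition; for cohorts far beyond ~10³ samples a subsampled or
  approximate backend would be needed.
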