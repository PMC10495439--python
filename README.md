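# predscreen

**Who predicts, and for whom?** PD-L1 expression is the standard biomarker
for selecting cancer patients for immune checkpoint inhibitors (ICI), but
its predictive value is wildly inconsistent across cancer types and
cohorts.  `predscreen` is a Python library for biostatisticians and
translational researchers that quantifies a biomarker's predictiveness,
screens the tumor transcriptome for genes that modulate it, builds a
linear predictiveness score, and evaluates biomarker-stratified efficacy
within the resulting patient subsets — with a synthetic-data module that
plants known effects so every stage has a parameter-recovery test.

## The statistics at the core

For a cancer type with pooled subgroup hazard ratios HR₊ and HR₋
(ICI vs standard-of-care in biomarker-positive/-negative patients), the
biomarker's predictiveness is the **hazard-ratio difference**

> HRD = (1 − HR₊) − (1 − HR₋) = HR₋ − HR₊ ,

with subgroups pooled by DerSimonian–Laird random effects and an
interaction p from the normal subgroup-difference test.  Candidate
modulator genes V are screened by Spearman correlation of per-cancer
medians with HRD (OS and PFS), then ranked within a treated cohort by the
Wald z of d in the Cox model

> hazard ∝ exp(a·PD-L1 + b·V + d·PD-L1·V) ,  covariates median-split;

positive d means high V erodes the biomarker's benefit association.  The
top modulator yields a **predictiveness score** PS = α·V + β (OLS of HRD
on gene medians, leave-one-out CV as diagnostic), and a median split of
PS defines Predictiveness-High (PH) vs Predictiveness-Low (PL) patients,
within which efficacy grids report Cox HRs, log-rank, Clopper–Pearson
ORR intervals and Fisher exact tests per PD-L1 stratum.

## Worked example

`examples/03_score_and_efficacy.py` simulates trials, an expression
panel, and a 1200-patient two-arm cohort with a planted
treatment×biomarker×modulator interaction, then runs score construction
and the efficacy grid:

```text
score model: PS = -0.82 x CDKN1C + 3.02  (LOOCV RMSE 0.107, 10 cancers)
{'PH': 616, 'PL': 584} patients per group

group     stratum endpoint  n_a  n_b    hr  ci_low  ci_high  logrank_p  orr_a  orr_b  fisher_p
   PH >=1% vs <1%       OS  193  107 0.881   0.650    1.194      0.414    NaN    NaN       NaN
   PH >=1% vs <1%      ORR  193  107   NaN     NaN      NaN        NaN  0.207  0.084     0.005
   PL >=1% vs <1%       OS  220   80 1.261   0.925    1.719      0.142    NaN    NaN       NaN
   PL >=1% vs <1%      ORR  220   80   NaN     NaN      NaN        NaN  0.141  0.100     0.439
```

Reading it: the fitted line (slope −0.82, intercept 3.02) recovers the
planted coefficients (−0.76, 2.81) up to simulation noise.  In the PH
group, PD-L1 ≥ 1% patients on ICI fare better than PD-L1 < 1% patients
(OS HR 0.88; ORR 21% vs 8%, Fisher p = 0.005); in the PL group the
direction reverses (OS HR 1.26) and the response advantage vanishes —
the planted context-dependent predictiveness, recovered end to end.

The other examples cover the meta-analysis stage (`01`), the two-step
modulator screen (`02`), TME signatures/consensus clustering (`04`), and
the file-based pipeline with its run manifest (`05`).  A thin CLI wraps
the same stages:

```bash
predscreen run-all --seed 7 --out-dir runs/demo
predscreen simulate --preset null --seed 7 --out-dir runs/null
```

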