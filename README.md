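# proteomr

Forecasting off-target drug effects by combining trial proteomics with
two-sample Mendelian randomization (MR).

## The problem

Late-stage drug failures are often caused by off-target adverse effects
that only surface once thousands of patients have been exposed. Proteomic
profiling in an early randomized trial shows *which* plasma proteins a
drug perturbs within months; what it cannot show is whether those
perturbations will *cause* harm years later. `proteomr` closes that gap
with human genetics: for every drug-perturbed protein it estimates the
causal effect of circulating protein level on a panel of health outcomes
from GWAS summary statistics, orients each estimate to the direction the
protein actually moved in the trial, and asks whether the genetically
predicted effect is concordant with what the trial observed. Reverse MR
(outcome → proteome) then separates proteins that *mediate* adverse
effects from proteins that merely *respond* to them.

The package is aimed at drug-safety and genetic-epidemiology analysts who
have (a) a trial protein-change table (log2-fold changes with FDR
p-values), (b) cis-pQTL summary statistics from a discovery and an
estimation study, and (c) outcome GWAS summary statistics.

## The model

For variant *j*, let β̂<sub>Xj</sub> (SE σ<sub>Xj</sub>) be its effect on
protein level and β̂<sub>Yj</sub> (SE σ<sub>Yj</sub>) its effect on the
outcome, from non-overlapping samples. Each independent cis-pQTL gives a
Wald ratio β̂<sub>Yj</sub>/β̂<sub>Xj</sub>; the primary estimator is the
fixed-effects inverse-variance weighted (IVW) combination

&nbsp;&nbsp;β̂ = Σ<sub>j</sub> β̂<sub>Xj</sub> β̂<sub>Yj</sub> σ<sub>Yj</sub>⁻² / Σ<sub>j</sub> β̂<sub>Xj</sub>² σ<sub>Yj</sub>⁻² ,
&nbsp;&nbsp;SE(β̂) = (Σ<sub>j</sub> β̂<sub>Xj</sub>² σ<sub>Yj</sub>⁻²)<sup>−1/2</sup> ,

i.e. weighted least squares of outcome effects on exposure effects
through the origin. Weighted-median, weighted-mode and an RSS-based
outlier test with outlier-corrected IVW (the MR-PRESSO procedure) are
implemented as sensitivity analyses that progressively relax the
no-horizontal-pleiotropy assumption.

Instruments are built per protein by a fixed chain: cis-window +
genome-wide significance (p < 5×10⁻⁸) selection in the discovery study →
greedy LD clumping (r² < 0.001 across 10,000 kb) → effect extraction from
the independent estimation study (avoiding winner's curse) → removal of
weak instruments (F = (β/σ)² < 10) → removal of variants more strongly
associated with another protein. Estimates are Bonferroni-corrected over
the number of protein-outcome tests actually produced, oriented to the
trial's protein direction (sign-flipped for proteins the drug lowered),
and classified concordant/discordant against the trial's trait changes.

## Worked example

The packaged reference table holds 32 significant protein-outcome MR
results from the torcetrapib (ILLUMINATE) case study. Replaying it
through the orientation + concordance engine:

```bash
python examples/01_concordance_replay.py
```

prints, after the per-row table:

```
all 19 printed flags reproduced: True
significant_proteins: 17
concordant_proteins: 7
blood_pressure_proteins: 6
blood_pressure_concordant_proteins: 4
annotated_rows: 19
```

Of the 95 analyzable drug-perturbed proteins, 17 causally affect at least
one outcome; 7 act in the same direction as the trial's observed trait
changes, and 4 of the 6 blood-pressure proteins (MRC2, PDE5A, SPON1,
TIE1) are concordant with the blood-pressure rise seen in the trial —
the drug's hallmark adverse effect, recovered from genetics plus
three-month proteomics alone. `examples/02_estimators.py`,
`03_instrument_selection.py` and `04_full_pipeline.py` demonstrate the
estimators, the instrument filter chain, and a full synthetic
simulate → forward → reverse → classify round trip (also available as the
`proteomr` CLI: `simulate`, `forward`, `reverse`, `classify`, `report`).

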