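# Methods

## Framework

`proteomr` triangulates three sources of evidence about a drug's
off-target effects: (1) a randomized trial's proteomic change table
(which proteins moved, and which way), (2) cis-pQTL GWAS summary
statistics (genetic instruments for each protein), and (3) outcome GWAS
summary statistics. The inference chain is:

1. **Aptamer resolution.** When several aptamers map to one protein, the
   one with the smallest discovery-study pQTL p-value is kept (ties break
   lexicographically by SeqID).
2. **On-target exclusion.** Proteins whose trial changes are explained by
   the drug's intended lipid effects are set aside: each lipid's causal
   effect on each protein is estimated by IVW MR and a protein is
   "on-target" if any lipid effect passes Bonferroni at α = 0.05 over all
   lipid × protein tests. The threshold is symmetric with the main
   analysis's correction; it is configurable because the exclusion rule's
   exact significance level is an analysis choice, not a property of the
   data.
3. **Instrument selection** (per protein, fixed order): cis-region +
   significance selection in the discovery study → LD clumping → effect
   extraction from the estimation study → F filter → cross-protein
   specificity filter. Every stage logs (n_in, n_out), so stage-wise
   conservation is checkable on any run.
4. **Forward MR** of every protein on every outcome; fixed-effects IVW
   primary (Wald ratio when a single instrument survives), sensitivity
   estimators where instrument counts permit (median/mode ≥ 3,
   RSS outlier test ≥ 4). Bonferroni over the number of estimates
   actually produced — not over the nominal protein × outcome grid —
   because pairs without a valid instrument never become tests.
5. **Orientation and concordance.** Raw estimates are per SD *increase*
   in protein; estimates for proteins the drug lowered are sign-flipped
   so every estimate reads "per SD change in the trial's direction". A
   significant estimate is concordant (1) if it points the same way as
   the trait change observed in the trial's active arm, discordant (0)
   otherwise, NA where the trial has no annotation for that trait.
6. **Reverse MR** of every outcome on the proteome, using genome-wide
   significant outcome instruments clumped with the same parameters (no
   cis restriction — cis is a protein-side concept). Per-outcome
   significant protein sets feed an upset-style intersection count table.
7. **Mediator classification.** Forward-significant ∧ ¬reverse-significant
   → upstream mediator; both → bidirectional; reverse only → downstream
   consequence.

## Estimators

All estimators consume harmonized per-variant pairs
(β̂_Xj, σ_Xj, β̂_Yj, σ_Yj) for approximately independent variants.

- **Wald ratio**: β̂_Yj/β̂_Xj with first-order delta SE σ_Yj/|β̂_Xj|. The
  first-order form ignores exposure-side error, matching the fixed-effects
  IVW weighting; a second-order correction
  √(σ_Yj²/β̂_Xj² + β̂_Yj²σ_Xj²/β̂_Xj⁴) is available behind a flag.
- **Fixed-effects IVW**: the weighted least-squares-through-origin
  solution given in the README; Cochran's Q on n−1 df reported as a
  heterogeneity diagnostic. Binary-outcome effects are log-odds
  throughout; no attenuation correction is applied.
- **Weighted median**: weights w_j = β̂_Xj²/σ_Yj² (the inverse first-order
  ratio variances), normalized; the estimate sits where the cumulative
  standardized weight crosses 0.5, interpolating linearly between adjacent
  order statistics (midpoint convention: the j-th sorted ratio carries
  cumulative weight Σ_{k≤j} w_k − w_j/2). Consistent while valid
  instruments hold > 50% of weight.
- **Weighted mode**: arg-max of a weighted normal-kernel density over the
  ratios, bandwidth = factor × 0.9·min(sd, 1.4826·MAD)·n^(−1/5) (modified
  Silverman rule on the ratio estimates), evaluated on a 512-point grid
  spanning the ratio range ± 2 bandwidths. Degenerate inputs (all ratios
  equal, or zero spread) return the common ratio. Consistent when the
  largest cluster of instruments is valid.
- **Pleiotropy RSS test with outlier correction** (the MR-PRESSO
  procedure): observed RSS = Σ_j w_j(β̂_Yj − β̂_(−j)β̂_Xj)² with w_j =
  σ_Yj⁻² and β̂_(−j) the leave-one-out IVW slope, compared against a
  parametric null: β̂*_Yj ~ N(β̂_(−j)β̂_Xj, σ_Yj) with leave-one-out slopes
  recomputed per draw, empirical p with the +1 correction. The null draws
  **condition on the observed exposure effects** rather than resampling
  them: the fixed-effects weighting already treats β̂_X as known, and
  resampling the exposure side inflates the null RSS, making the global
  test conservative (empirically ~0.026 instead of 0.05 at the nominal
  level in our calibration runs; conditioning restores ~0.04-0.05).
  Per-variant outlier p-values are the analogous per-residual tail
  probabilities, Bonferroni-multiplied by n, flagged below 0.05. The
  reported estimate is the IVW on unflagged variants (identical to the
  full-set IVW when nothing is flagged), plus a distortion test comparing
  the raw-minus-corrected shift against random same-size removals.

Bootstrap SEs (median, mode) use a parametric bootstrap — β̂_Xj and β̂_Yj
resampled from N(β̂, σ) per variant — with 1,000 replicates by default;
`bootstrap_reps=0` skips the bootstrap and returns only the point
estimate. All stochastic components take explicit seeds.

## Harmonization

Outcome records are aligned to the exposure's effect allele: swapped
alleles negate the outcome beta and complement its EAF; alleles that only
match after strand complementation are complemented first; everything
else is dropped as irreconcilable, with a per-variant reason log.
Palindromic variants (A/T, C/G) are kept only when both EAFs are present,
on the same side of 0.5 after alignment, and outside
[limit, 1 − limit] with limit defaulting to 0.42 — a widely used
harmonization convention, configurable because published pipelines vary.
A palindromic variant with EAF exactly 0.5 is always dropped: the four
strand/flip resolutions are indistinguishable there. Non-palindromic
variants with missing EAF are kept (alleles suffice); palindromic ones
are not.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `p_instrument` | 5×10⁻⁸ | genome-wide significance for selection (strict `<`) |
| `cis_window_bp` | 500,000 | window around the gene body defining "cis" |
| `clump_r2` | 0.001 | maximum pairwise r² after clumping (strict `<`) |
| `clump_window_kb` | 10,000 | pairwise distance within which r² is enforced |
| `f_min` | 10 | weak-instrument cut; F exactly 10 is retained |
| `alpha` | 0.05 | family-wise error level for Bonferroni |
| `palindrome_eaf_limit` | 0.42 | ambiguity band for palindromic variants |

The cis window is an explicit parameter because "cis" has no universal
definition; ±500 kb matches common pQTL practice. Clumping ties on
p-value break by genomic position then variant id, which makes the
greedy selection invariant to input row order. The per-protein
F statistic exported next to instrument counts is the minimum across a
protein's instruments (the binding value for the F ≥ 10 filter); per-
variant F values are always available on the instrument set.

## Synthetic data

The generator emulates the statistical structure the framework assumes,
with known ground truth. Per protein, `variants_per_protein` cis variants
receive true per-allele effects drawn from `pqtl_effect_range`
(0.15-0.5 SD, random sign) at allele frequencies U(0.05, 0.95); a
discovery and an estimation study observe them with independent noise,
SE = 1/√(2f(1−f)n) for a unit-variance trait, so F statistics scale
linearly with n and the F ≥ 10 filter bites realistically. Default
sample sizes (7,213 discovery; 35,559 estimation; 100,000 outcome) match
the scale of the studies the framework targets. Outcome GWAS effects are
θ·β_X plus a horizontal-pleiotropy term α drawn once per variant-outcome
pair (none / balanced zero-mean / directional positive-mean / outlier
subset), plus noise. Each outcome also owns `outcome_variants` loci of
its own, far from every gene body, whose protein-side effects are ρ·γ
when the scenario declares a reverse outcome→protein effect ρ — this is
what gives reverse MR something real to detect or correctly reject.
Trial log2-fold changes follow a per-protein rule; each outcome's trait
direction is the sign of Σ_p θ_p·log2fc_p. LD is block-diagonal within
each locus. Alleles are drawn from strand-unambiguous pairs only, so
harmonizing simulated bundles is lossless; palindromic handling is
exercised by dedicated unit tests instead.

What the generator does **not** emulate: realistic human LD maps,
case-control ascertainment, sample overlap between studies, assay
technical variation, or correlated pleiotropy (α correlated with β_X,
violating InSIDE). Passing tests therefore show the machinery is correct
under the stated model, not that real-data results are robust to those
harder violations.

The default recovery scenario (20 proteins × 5 instruments, true effects
cycling through {0, ±0.1, ±0.3}) runs 500 replicates in the test suite;
these sizes keep the full suite within a few minutes on one CPU while
leaving Monte-Carlo error well below the effects being checked. Note one
deliberate calibration: directional pleiotropy only biases the IVW when
instrument-exposure effects share a sign convention (otherwise the
variant-level shifts cancel in the slope), so the pleiotropy scenarios
set `pqtl_positive_effects=True` — the orientation real analyses impose
by coding effect alleles as exposure-increasing. For the contaminated
weighted-median check, "within Monte-Carlo error of truth" is assessed on
the estimator's own scale (|mean − θ| < 3·sd of the estimator): the
weighted median's finite-sample bias under contamination is a fixed
multiple of its per-replicate sd (≈ Φ⁻¹(0.5/(1−f)) · sd(ratio) for
contaminated weight fraction f), so no implementation can drive it below
an arbitrary multiple of sd/√R as R grows; the unbiased no-pleiotropy IVW
check uses the stricter mean scale (3·sd/√R), where it is attainable.

## Reference table

The packaged 32-row table transcribes the published torcetrapib
case-study results (protein, aptamer SeqID, outcome, instrument count,
F statistic, trial log2-fold change, trait direction, oriented MR
estimate, concordance flag, outcome type). The replay path maps each
printed beta back to the per-SD-increase scale, re-runs orientation and
classification, and compares flags; the headline counts (17 significant
proteins, 7 concordant, 6 blood-pressure proteins, 4 BP-concordant) are
all recomputed, never hard-coded. The source material is internally
inconsistent about the concordant-protein count (its summary says six
where its results and table support seven distinct proteins); the
table-derived count of seven is what this package reproduces.

## Determinism and bookkeeping

Every run writes a manifest: effective configuration, input SHA-256
checksums, seeds, and per-stage (in, retained, excluded) counts with
in = retained + excluded enforced at write time. Reruns with identical
config and seeds produce byte-identical result tables; the manifest is
identical up to its single wall-clock timestamp line, which the
comparison helper excludes. Log2-fold changes of exactly zero have no
direction: such proteins are excluded from orientation and concordance
with a logged reason rather than silently assigned a side.

## Limitations

- Real pQTL and outcome GWAS data must be supplied by the user; the
  package validates and harmonizes them but ships no external data
  beyond the reference table.
- No MR-Egger, multivariable MR, Steiger filtering, or colocalization;
  no proxy-variant lookup, liftover, or LD computation from genotypes.
- Reverse MR inherits a genuine identifiability limit: a protein's own
  pQTLs can enter an outcome's instrument set when the protein strongly
  affects that outcome, which makes truly forward-causal proteins look
  bidirectional. The synthetic examples size forward effects below
  per-variant genome-wide significance in the outcome GWAS to keep the
  demonstration clean; real analyses should read "bidirectional" labels
  with this artifact in mind.
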