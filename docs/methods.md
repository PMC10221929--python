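# Methods

## Causal model and assumptions

The package estimates the effect of an exposure X (standardized relative
abundance of a gut taxon, or a circulating metabolite) on a binary outcome Y
(IgAN) from two independent GWAS summary datasets, using genetic variants as
instruments. The usual MR assumptions apply: each instrument is associated
with X (relevance, enforced by the p-value and F screens), independent of
confounders, and affects Y only through X (exclusion restriction — probed,
not guaranteed, by the sensitivity battery). All outcome effects are
log-odds; estimates exponentiate to odds ratios per SD of exposure.

## Instrument screening

The cascade runs in a fixed order, each step recording its exclusions in an
audit trail so candidates are conserved:

1. **Significance** — keep p < 1×10⁻⁵ (locus-wide); metabolites use 5×10⁻⁵
   because genome-wide instruments are too scarce for them.
2. **LD clumping** — greedy: keep the most significant remaining variant,
   discard neighbours with r² > 0.001; when a pair is missing from the LD
   table, a 10,000 kb same-chromosome window is used as a distance
   fallback. Ties on p break lexicographically on variant id, making the
   result deterministic. The output is p-rank-order dependent by
   construction; every retained pair satisfies the r² bound.
3. **Strength** — per-variant R² = 2·EAF·(1−EAF)·β² (standardized-trait
   scale) and F = (R²/(1−R²))·((N−K−1)/K) with K = 1: screening happens
   per instrument, before the final instrument count is known. Variants
   with F < 10 are dropped. Note the F formula is sometimes printed with
   the denominator (R²−1), which is negative for R² < 1; the positive
   denominator form is the one the F ≥ 10 convention presupposes and is
   what we implement.
4. **Frequency** — minor-allele frequency ≥ 0.01 by default (symmetric in
   EAF; a literal effect-allele-only mode is available via a flag, since
   published descriptions are often ambiguous on this point).
5. **Outcome association** — instruments with outcome p < 0.05 are removed,
   as a guard against reverse causation and direct effects. This filter
   has a real cost: when the causal effect is genuine and instruments are
   strong, it preferentially removes the very instruments carrying the
   signal, attenuating the IVW estimate toward the null (the end-to-end
   synthetic study shows ORs of ~1.25–1.4 recovered from a generating OR
   of 1.5). We keep it because it is part of the study design being
   implemented; it can be disabled by setting the cut to 0.
6. **Confounder blacklist** — a static variant list standing in for a
   Phenoscanner-style lookup (no live queries).

## Harmonization

Outcome effects are aligned onto the exposure's effect allele: matching
coding is kept, swapped coding negates the outcome beta, and opposite-strand
(complement) codings are resolved the same way. Palindromic variants (A/T,
C/G) are dropped when the exposure EAF is within 0.08 of 0.5 — the
conservative standard, since strand cannot be inferred at intermediate
frequency; outside that window the allele letters decide orientation.
The Wald-ratio SE uses the first-order delta approximation
se(β_Y)/|β_X|; the second-order term (which adds the exposure noise) is
omitted, the common default in summary-data MR.

## Estimators

* **IVW**: weighted mean of Wald ratios, w_j = 1/se(θ̂_j)². Default is
  multiplicative random effects — the SE scales by max(1, √(Q/(J−1))), so
  heterogeneity can only widen, never narrow, the interval. Fixed effects
  by flag. p-values are two-sided normal.
* **MR-Egger**: weighted least squares of β_Y on β_X with a free intercept,
  weights 1/se(β_Y)². Instruments are first oriented so every β_X > 0
  (negating both betas leaves the ratio unchanged). The residual scale is
  multiplicative random effects (scale-up only); p-values use t with J−2
  df, the convention for the two-parameter fit.
* **Weighted median**: ratios ordered ascending; standardized cumulative
  weight s_j = (Σ_{i≤j} w_i − w_j/2)/Σw; the estimate interpolates the
  ratio at s = 0.5. SE by parametric bootstrap: β_X and β_Y are resampled
  from their reported normal errors (default 1000 draws, seed required).
* **Weighted mode**: weighted Gaussian-kernel density over the ratios with
  bandwidth h = factor · 0.9 · min(sd, MAD/0.6745) · J^(−1/5) (a
  modified-Silverman rule; factor defaults to 1). The argmax is located on
  a 4096-point grid and polished with bounded scalar minimization; the
  bootstrap uses a 512-point grid without polishing, which is ample for a
  spread estimate. Degenerate (constant-ratio) inputs fall back to a small
  positive bandwidth so the mode is still defined.

## Sensitivity battery

* **Cochran's Q** around the fixed-effect IVW estimate, chi-square with
  J−1 df.
* **MR-PRESSO-style residual test**: observed RSS uses leave-one-out IVW
  fitted values; the null distribution is parametric (effects resampled
  from their reported errors around the leave-one-out fits); the global p
  is the add-one empirical tail (so never below 1/(n_sim+1); default
  n_sim = 1000). Per-variant residual p-values are Bonferroni-adjusted by
  J; the distortion test compares the IVW shift after removing flagged
  variants against shifts from removing random same-size subsets, and is
  only emitted when at least one outlier was found. If every instrument is
  flagged no corrected estimate exists and an error is raised.
* **Leave-one-out**: IVW excluding each instrument; a row is flagged on a
  sign change or on loss of nominal significance relative to the full fit.
* **Funnel table**: per-instrument (ratio, precision) pairs with method
  reference lines, ready for plotting; no rendering is attempted here.

## Multiple testing and verdicts

Bonferroni thresholds are per trait kind: 0.05 divided by 131 (genus), 35
(family), 20 (order), 16 (class), 9 (phylum) and 15 (metabolite). The
metabolite divisor is deliberately 15 — the value used in the source
analysis — even though only 12 metabolites are named there; both are
configurable, and the discrepancy is preserved rather than resolved.
Verdicts use strict inequalities: *significant* if p < α/m, *nominal* if
α/m ≤ p < α, else *null*. Reverse MR swaps roles (disease as exposure) and
screens disease instruments at genome-wide 5×10⁻⁸ by default (configurable),
since a disease GWAS ordinarily has genome-wide hits or nothing usable.

## Synthetic-data generator

`simulate_summary_pair` draws, per instrument: EAF ~ U(0.05, 0.95); true
effect γ_j ~ N(gamma_mean, gamma_sd²) on the standardized exposure;
observed β_X = γ_j + noise with se(β_X) = 1/√(2p(1−p)·n_exp); pleiotropy
α_j = 0 (none), N(0, alpha_sd²) (balanced), N(alpha_mean, alpha_sd²)
(directional) or correlated with γ_j at 0.6 (InSIDE-violating); and
β_Y = θγ_j + α_j + noise with se(β_Y) = 1/√(2p(1−p)·n_out·φ(1−φ)) for case
fraction φ — the standard large-sample approximations for a continuous
exposure GWAS and a binary-outcome GWAS. Sample sizes default to the real
data scales (n_exp = 18,340 microbiota GWAS; n_out = 628,000 outcome
meta-analysis, case fraction 0.03). Instruments are independent (identity
LD table) and placed ≥ 50 Mb apart per chromosome so distance-based clump
fallbacks also treat them as independent; clumping behaviour is tested with
purpose-built block fixtures instead. Palindromic allele pairs are avoided
so harmonization keeps every simulated instrument.

Default instrument strength is gamma_mean = 0.45, gamma_sd = 0.15. This is
the generator's definition of "strong instruments": it keeps the effects
bounded away from zero (sign flips would make oriented pleiotropy correlate
with strength) and puts I²_GX = var(γ)/(var(γ)+E[se²]) at ≈ 99%, the regime
in which Egger's no-measurement-error assumption effectively holds. With
weaker settings Egger acquires a visible regression-dilution bias — that is
a property of the estimator, not of the implementation, and the end-to-end
pipeline study deliberately uses a weaker, more realistic regime
(gamma_mean 0.15, sd 0.05, case fraction 0.0016) to exercise the screening
cascade as it would behave on real microbiome data.

What the generator does *not* emulate: LD between instruments, winner's
curse from in-sample selection, sample overlap between the two GWAS,
allele-frequency mismatch between populations, and non-normal effect
distributions. Passing tests therefore demonstrate correctness of the
machinery and the estimators' stated statistical properties under their
assumptions — not robustness to those real-data complications.

`simulate_clinical_cohort` draws per-group logit-normal abundances
(defaults: 10 IgAN at median ~0.20, 10 healthy controls at ~0.08, 5 other
glomerular disease at ~0.10, giving a population IgAN-vs-HC AUC of ≈ 0.88),
then generates 24-h albuminuria as a linear function of the *logit*
abundance plus Gaussian noise, standardized against the population mixture
moments so the population correlation with logit abundance equals the
target (default 0.85). Values are floored at zero, a > 4σ event under the
defaults, so the realized correlation is essentially exact; the calibration
is therefore on the logit scale, and the raw-abundance correlation is
slightly attenuated. eGFR is Gaussian per group (defaults mirroring the
cohort table: ~93/55/20 mL/min/1.73 m²) with an optional abundance slope,
zero by default.

## Clinical validation statistics

The ROC curve enumerates every observed score as a threshold under the
strict "score > cutoff" positivity rule; the trapezoidal AUC then equals
the all-pairs concordance statistic exactly (ties counted half). The
Youden cutoff maximizes sensitivity + specificity − 1 over observed
thresholds; ties break toward the higher threshold (the more specific
classifier), and a curve whose best J is 0 returns the lowest threshold
with a degeneracy flag. Pearson correlations use the t transform with n−2
df. Group comparisons dispatch on a Shapiro (per group) + Levene screen at
0.05: parametric (two-sample t-test / one-way ANOVA) only when every check
passes, otherwise rank-based (Wilcoxon rank-sum / Kruskal-Wallis); the
screen's p-values are reported for auditability. Count tables use the
chi-square test. AUC confidence intervals, where needed, are bootstrap
(no DeLong).

## Numerical and testing choices

Monte-Carlo checks use 200 replicates; calibration bands are [0.02, 0.10]
for nominal-5% tests, and recovery checks require the mean estimate within
2 Monte-Carlo SEs of truth — sizes chosen so the suite completes in seconds
while keeping the MC error small relative to the effects being verified. IVW and Egger are verified against independent
weighted-least-squares solutions to 1×10⁻¹⁰. The weighted-mode argmax is
verified against a 10⁵-point brute-force density grid. All generators are
pure functions of (parameters, seed); re-running any pipeline with the same
config reproduces its output byte for byte.

## Known limitations

* No proxy-SNP search, liftover, VCF parsing or in-sample LD estimation;
  LD is consumed as a precomputed pairwise table.
* No MR-RAPS, multivariable MR or Steiger filtering.
* The MR-PRESSO-style test follows the published structure (leave-one-out
  fits, parametric bootstrap, add-one p) but is an independent
  implementation; exact p-values differ from the R reference by Monte-Carlo
  noise.
* Small-cohort confusion metrics (n = 10 per group) are inherently coarse
  (multiples of 1/10); reported literature values that are not expressible
  that way cannot be reproduced exactly and are not asserted.
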