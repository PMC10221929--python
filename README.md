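# gutmr

Two-sample Mendelian randomization (MR) of gut microbiota and circulating
metabolites on immunoglobulin A nephropathy (IgAN), with a synthetic-data
module so the whole pipeline is testable offline, and the clinical
biomarker-validation statistics used to corroborate an MR hit in a small
patient cohort.

## Who this is for

Epidemiologists and biostatisticians who want a tested, reusable
implementation of the summary-statistic MR workflow applied to microbiome
exposures: screen genetic instruments from GWAS summary tables, estimate the
causal effect of each taxon (or metabolite) on disease risk with four
complementary estimators, run the standard sensitivity battery, correct for
multiple testing per taxonomic level, and probe reverse causation.

## The model

Each genetic variant *j* provides a Wald ratio estimate of the causal effect
θ of an exposure (standardized taxon abundance) on the outcome log-odds:

    θ̂_j = β̂_Yj / β̂_Xj,   se(θ̂_j) ≈ se(β̂_Yj) / |β̂_Xj|

Instruments pass a screening cascade before estimation: locus-wide
significance (p < 1×10⁻⁵; 5×10⁻⁵ for metabolites), greedy LD clumping
(r² < 0.001 within 10,000 kb), per-variant strength F ≥ 10 with
R² = 2·EAF·(1−EAF)·β², a minor-allele-frequency floor of 0.01, exclusion of
variants directly associated with the outcome (p < 0.05), and a static
confounder blacklist.

Four estimators combine the Wald ratios:

* **IVW** — inverse-variance-weighted mean, Σw_jθ̂_j / Σw_j with
  w_j = 1/se(θ̂_j)²; identical to weighted regression of β̂_Y on β̂_X with the
  intercept constrained to zero. Multiplicative random effects by default.
* **MR-Egger** — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy, the slope the causal effect
  under the InSIDE assumption.
* **Weighted median** — the 50% point of the weight-ordered ratio
  distribution; consistent when ≥ 50% of weight is on valid instruments.
* **Weighted mode** — argmax of a weighted Gaussian-kernel density over the
  ratios; consistent when the largest cluster of instruments is valid.

Diagnostics: Cochran's Q heterogeneity test, the Egger intercept test,
an MR-PRESSO-style global/outlier/distortion test, leave-one-out
re-estimation and funnel tables. Verdicts use a per-taxonomic-level
Bonferroni scheme (0.05/131 genera, /35 families, /20 orders, /16 classes,
/9 phyla, /15 metabolites): p below the corrected threshold is
*significant*, between the threshold and 0.05 *nominal*, otherwise *null*.

The clinical-validation module evaluates a taxon's relative abundance as a
diagnostic biomarker: empirical ROC/AUC, Youden-index cutoff,
confusion-matrix metrics under a strict "abundance > cutoff" rule, Pearson
correlation with 24-h albuminuria and eGFR, and group-comparison dispatch
(t-test/ANOVA vs rank tests after a normality and homogeneity screen).

## Worked example

Simulate a two-sample dataset with a true odds ratio of 1.2 per SD of
abundance, harmonize the two sides onto a shared effect allele, and run the
estimator battery:

```python
import numpy as np
from gutmr import (SimTruth, simulate_summary_pair, harmonize, ivw, egger,
                   weighted_median, weighted_mode, cochran_q)

truth = SimTruth(theta=np.log(1.2), J=30, seed=7)
exposure, outcome, ld, _ = simulate_summary_pair(truth)
instruments = harmonize(exposure, outcome)
for est in (ivw(instruments), egger(instruments),
            weighted_median(instruments, seed=7),
            weighted_mode(instruments, seed=7)):
    print(f"{est.method:16s} OR {est.or_:.2f} "
          f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f})  p = {est.pvalue:.1e}")
q, df, p = cochran_q(instruments, ivw(instruments).beta)
print(f"Cochran's Q = {q:.1f} on {df} df (p = {p:.2f})")
```

prints

```
ivw              OR 1.20 (95% CI 1.19-1.21)  p = 1.7e-296
egger            OR 1.20 (95% CI 1.16-1.24)  p = 1.9e-11
weighted_median  OR 1.20 (95% CI 1.18-1.22)  p = 4.8e-154
weighted_mode    OR 1.20 (95% CI 1.18-1.23)  p = 3.0e-64
Cochran's Q = 22.4 on 29 df (p = 0.80)
```

All four estimators recover the generating odds ratio of 1.20 (the CIs are
narrow because the simulated instruments are deliberately strong), and Q
shows no excess heterogeneity, as expected without pleiotropy.

## Command line

```sh
gutmr simulate --out data/ --theta 0.18 --seed 3   # synthetic study inputs
gutmr run      --config config.yaml --out results/ # forward MR pipeline
gutmr reverse  --config config.yaml --out results/ # disease as exposure
gutmr validate --cohort data/cohort.csv --out validation.json
```

The config is a YAML file naming exposure/outcome summary-statistic TSVs,
the LD table, the trait-level manifest and any threshold overrides; every
random operation takes its seed from the config.

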