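"""Synthetic-data generators emulating the study's inputs.

Three generators, each a pure function of (parameters, seed):

* :func:`simulate_summary_pair` — two-sample GWAS summary statistics under a
  known causal model.  Instrument effects on the (standardized) exposure are
  drawn per variant; the outcome is a disease trait whose log-odds respond to
  the exposure through a configurable causal effect, optionally contaminated
  by balanced, directional, or InSIDE-violating horizontal pleiotropy.
  Standard errors follow the usual large-sample formulas given the sample
  sizes, allele frequencies and (for the binary outcome) the case fraction.
* :func:`simulate_taxa_manifest` — trait ids across the five taxonomic
  levels of the microbiota GWAS (default 131 genera, 35 families, 20 orders,
  16 classes, 9 phyla = 211 traits).
* :func:`simulate_clinical_cohort` — a small clinical table (IgAN patients,
  healthy controls, other glomerular disease) with per-subject taxon
  relative abundance, 24-h albuminuria and eGFR, with a controllable
  abundance-albuminuria correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from gutmr.instruments import LDTable
from gutmr.sumstats import SummaryDataset, VariantAssociation

PLEIOTROPY_MODES = ("none", "balanced", "directional", "inside_violating")

#: taxonomic composition of the microbiota exposure panel
DEFAULT_TAXA_COUNTS = {
    "genus": 131,
    "family": 35,
    "order": 20,
    "class": 16,
    "phylum": 9,
}


@dataclass(frozen=True)
class SimTruth:
    """Generating parameters of one synthetic two-sample dataset.

    theta is the true causal effect on the outcome log-odds per SD of
    exposure; gamma_* parameterize the per-variant instrument effects;
    alpha_* the horizontal-pleiotropy effects.  n_exp/n_out mirror the
    microbiota GWAS (18,340) and the disease meta-analysis (628,000) sample
    sizes; case_fraction sets the outcome's case share for the binary-trait
    SE approximation.
    """

    theta: float = 0.0
    J: int = 30
    gamma_mean: float = 0.45
    gamma_sd: float = 0.15
    pleiotropy_mode: str = "none"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    inside_corr: float = 0.6
    n_exp: int = 18_340
    n_out: int = 628_000
    case_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.gamma_sd < 0 or self.alpha_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0,1)")


def _clip_p(p: np.ndarray) -> np.ndarray:
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_summary_pair(
    truth: SimTruth,
    trait_id: str = "sim_exposure",
    trait_kind: str = "genus",
) -> tuple[SummaryDataset, SummaryDataset, LDTable, SimTruth]:
    """Generate an exposure/outcome summary-statistic pair under ``truth``.

    Per instrument j: true effect γ_j ~ N(gamma_mean, gamma_sd²); observed
    exposure beta = γ_j + N(0, se_exp_j²) with se_exp_j = 1/sqrt(2p(1−p)n_exp)
    for a standardized continuous exposure.  Pleiotropy α_j is 0 (none),
    N(0, alpha_sd²) (balanced), N(alpha_mean, alpha_sd²) (directional), or
    correlated with γ_j at ``inside_corr`` (inside_violating).  The outcome
    log-odds effect is θγ_j + α_j + N(0, se_out_j²) with
    se_out_j = 1/sqrt(2p(1−p)·n_out·φ(1−φ)) for case fraction φ.

    Instruments are simulated as independent (identity LD table) on distinct
    chromosomes/positions; clumping tests use purpose-built block fixtures
    instead.
    """
    rng = np.random.default_rng(truth.seed)
    j = truth.J
    eaf = rng.uniform(0.05, 0.95, size=j)
    gamma = rng.normal(truth.gamma_mean, truth.gamma_sd, size=j)

    if truth.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    elif truth.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, truth.alpha_sd, size=j)
    elif truth.pleiotropy_mode == "directional":
        alpha = rng.normal(truth.alpha_mean, truth.alpha_sd, size=j)
    else:  # inside_violating: alpha correlated with instrument strength
        rho = truth.inside_corr
        z = rng.normal(size=j)
        gamma_std = (gamma - gamma.mean()) / (gamma.std() or 1.0)
        alpha = truth.alpha_mean + truth.alpha_sd * (
            rho * gamma_std + np.sqrt(1.0 - rho ** 2) * z
        )

    var_g = 2.0 * eaf * (1.0 - eaf)
    se_exp = 1.0 / np.sqrt(var_g * truth.n_exp)
    phi = truth.case_fraction
    se_out = 1.0 / np.sqrt(var_g * truth.n_out * phi * (1.0 - phi))

    beta_exp = gamma + rng.normal(0.0, se_exp)
    beta_out = truth.theta * gamma + alpha + rng.normal(0.0, se_out)

    p_exp = _clip_p(2.0 * stats.norm.sf(np.abs(beta_exp) / se_exp))
    p_out = _clip_p(2.0 * stats.norm.sf(np.abs(beta_out) / se_out))

    alleles = np.array(list("ACGT"))
    exp_records, out_records = [], []
    for i in range(j):
        a_idx = rng.integers(0, 4)
        # avoid palindromic pairs so harmonization keeps every instrument
        b_choices = [b for b in "ACGT"
                     if b != alleles[a_idx] and b != {"A": "T", "T": "A",
                                                      "C": "G", "G": "C"}[alleles[a_idx]]]
        eff = str(alleles[a_idx])
        oth = str(b_choices[rng.integers(0, len(b_choices))])
        common = dict(
            variant_id=f"rs{i + 1:07d}",
            effect_allele=eff,
            other_allele=oth,
            chrom=str(i % 22 + 1),
            # same-chromosome variants sit 50 Mb apart so distance-based
            # clump fallbacks treat them as independent
            pos=1_000_000 + 50_000_000 * (i // 22),
        )
        exp_records.append(VariantAssociation(
            eaf=float(eaf[i]), beta=float(beta_exp[i]), se=float(se_exp[i]),
            pvalue=float(p_exp[i]), n=truth.n_exp, **common,
        ))
        out_records.append(VariantAssociation(
            eaf=float(eaf[i]), beta=float(beta_out[i]), se=float(se_out[i]),
            pvalue=float(p_out[i]), n=truth.n_out, **common,
        ))

    exposure = SummaryDataset(trait_id, trait_kind, exp_records)
    outcome = SummaryDataset("sim_outcome", "disease", out_records)
    return exposure, outcome, LDTable(), truth


def write_truth_sidecar(truth: SimTruth, path: str | Path) -> None:
    """Echo the generating parameters to a JSON sidecar for recovery tests."""
    Path(path).write_text(json.dumps(asdict(truth), indent=2) + "\n")


def simulate_taxa_manifest(
    counts: dict[str, int] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic exposure manifest: one row per trait with its level.

    Defaults to the microbiota panel composition (211 taxa across five
    levels).  Returns a DataFrame with columns trait_id, level.
    """
    counts = dict(DEFAULT_TAXA_COUNTS) if counts is None else dict(counts)
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be >= 0")
    rows = []
    for level, count in counts.items():
        for i in range(count):
            rows.append({"trait_id": f"{level}_{i + 1:03d}", "level": level})
    return pd.DataFrame(rows, columns=["trait_id", "level"])


@dataclass
class ClinicalCohort:
    """Per-subject clinical validation table."""

    table: pd.DataFrame  # subject_id, group, abundance, albuminuria_g_24h, egfr

    def __post_init__(self) -> None:
        ab = self.table["abundance"]
        if ((ab < 0) | (ab > 1)).any():
            raise ValueError("abundances must lie in [0,1]")
        if (self.table["egfr"] <= 0).any():
            raise ValueError("eGFR must be positive")

    def group_sizes(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()


#: group-level defaults mirroring the validation cohort: 10 IgAN patients,
#: 10 healthy controls, 5 other glomerular disease; abundance distributions
#: chosen so IgAN sits higher (logit-normal means on the logit scale)
DEFAULT_GROUP_SIZES = {"IgAN": 10, "HC": 10, "OtherGN": 5}
DEFAULT_ABUNDANCE_LOGIT = {
    "IgAN": (-1.4, 0.6),   # median abundance ~0.20
    "HC": (-2.4, 0.6),     # median ~0.08
    "OtherGN": (-2.2, 0.6),
}
DEFAULT_EGFR = {"IgAN": (55.0, 13.0), "HC": (93.0, 5.0), "OtherGN": (20.0, 8.0)}


def simulate_clinical_cohort(
    group_sizes: dict[str, int] | None = None,
    abundance_logit: dict[str, tuple[float, float]] | None = None,
    target_albuminuria_r: float = 0.85,
    albuminuria_mean: float = 2.0,
    albuminuria_sd: float = 0.5,
    egfr_params: dict[str, tuple[float, float]] | None = None,
    egfr_abundance_slope: float = 0.0,
    seed: int = 0,
) -> ClinicalCohort:
    """Generate a clinical cohort with a controllable biomarker signal.

    Abundances are logit-normal per group.  Albuminuria is linear in the
    logit abundance plus Gaussian noise, standardized so the population
    Pearson correlation with logit abundance equals ``target_albuminuria_r``
    (values are shifted to ``albuminuria_mean`` g/24h with overall SD
    ``albuminuria_sd`` and floored at zero; with the defaults the floor is a
    >4-sigma event so the realized correlation is essentially exact).  eGFR
    is Gaussian per group with an optional abundance dependence.
    """
    if not -1.0 < target_albuminuria_r < 1.0:
        raise ValueError("target correlation must be in (-1, 1)")
    if albuminuria_sd <= 0:
        raise ValueError("albuminuria_sd must be positive")

    group_sizes = dict(DEFAULT_GROUP_SIZES) if group_sizes is None else dict(group_sizes)
    abundance_logit = (dict(DEFAULT_ABUNDANCE_LOGIT) if abundance_logit is None
                       else dict(abundance_logit))
    egfr_params = dict(DEFAULT_EGFR) if egfr_params is None else dict(egfr_params)

    rng = np.random.default_rng(seed)
    rows = []
    # population moments of the logit-abundance mixture, for standardization
    total = sum(group_sizes.values())
    mix_mean = sum(group_sizes[g] * abundance_logit[g][0] for g in group_sizes) / total
    mix_var = sum(
        group_sizes[g] * (abundance_logit[g][1] ** 2
                          + (abundance_logit[g][0] - mix_mean) ** 2)
        for g in group_sizes
    ) / total
    mix_sd = float(np.sqrt(mix_var))

    r = target_albuminuria_r
    subj = 0
    for group, size in group_sizes.items():
        mu, sd = abundance_logit[group]
        z = rng.normal(mu, sd, size=size)
        abundance = 1.0 / (1.0 + np.exp(-z))
        u = (z - mix_mean) / mix_sd
        eps = rng.normal(size=size)
        alb = albuminuria_mean + albuminuria_sd * (
            r * u + np.sqrt(1.0 - r ** 2) * eps
        )
        alb = np.maximum(alb, 0.0)
        e_mu, e_sd = egfr_params[group]
        egfr = rng.normal(e_mu, e_sd, size=size) + egfr_abundance_slope * u
        egfr = np.maximum(egfr, 5.0)
        for i in range(size):
            subj += 1
            rows.append({
                "subject_id": f"S{subj:05d}",
                "group": group,
                "abundance": float(abundance[i]),
                "albuminuria_g_24h": float(alb[i]),
                "egfr": float(egfr[i]),
            })
    return ClinicalCohort(pd.DataFrame(rows))
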