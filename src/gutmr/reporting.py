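"""Multiple-testing scheme, significance classification and pipeline
orchestration.

The Bonferroni correction is applied per taxonomic level: the threshold for
an exposure of kind *k* is alpha divided by the number of traits tested at
that level (131 genera, 35 families, 20 orders, 16 classes, 9 phyla, 15
metabolites by default).  An IVW p-value below the corrected threshold is
*significant*; in [threshold, alpha) it is *nominal*; otherwise *null*.

:func:`run_pipeline` executes the full forward analysis for every exposure
in a run configuration (screen → harmonize → estimate → diagnose →
classify) and :func:`run_reverse` repeats it with the disease as the
exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from gutmr import estimators as est
from gutmr.instruments import LDTable, select_instruments, read_blacklist
from gutmr.sensitivity import SensitivityReport, sensitivity_report
from gutmr.sumstats import (
    SummaryDataset,
    harmonize,
    read_summary_table,
)

logger = logging.getLogger(__name__)

VERDICTS = ("significant", "nominal", "null")

#: per-level test counts behind the default Bonferroni scheme
DEFAULT_TEST_COUNTS = {
    "genus": 131,
    "family": 35,
    "order": 20,
    "class": 16,
    "phylum": 9,
    "metabolite": 15,
}


@dataclass(frozen=True)
class BonferroniScheme:
    """Per-trait-kind multiple-testing divisors with a shared alpha."""

    m: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TEST_COUNTS)
    )
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if any(v < 1 for v in self.m.values()):
            raise ValueError("test counts must be >= 1")


def bonferroni_threshold(scheme: BonferroniScheme, kind: str) -> float:
    """Corrected significance threshold alpha/m for a trait kind."""
    if kind not in scheme.m:
        raise KeyError(f"no test count configured for trait kind {kind!r}")
    return scheme.alpha / scheme.m[kind]


def classify(est_: est.MREstimate, threshold: float, alpha: float = 0.05) -> str:
    """Verdict for one estimate: significant / nominal / null.

    ``significant`` when p < threshold; ``nominal`` when
    threshold <= p < alpha; ``null`` otherwise.  Comparisons are strict at
    both boundaries, so p exactly equal to the corrected threshold is
    nominal and p exactly equal to alpha is null.
    """
    if threshold > alpha:
        raise ValueError("corrected threshold cannot exceed alpha")
    p = est_.pvalue
    if p < threshold:
        return "significant"
    if p < alpha:
        return "nominal"
    return "null"


@dataclass
class ClassifiedResult:
    """All outputs of the pipeline for one exposure."""

    trait_id: str
    trait_kind: str
    primary: est.MREstimate | None  # IVW (or Wald for single instruments)
    estimates: dict[str, est.MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    verdict: str = "null"
    n_instruments: int = 0
    failure: str | None = None  # e.g. "no instruments"
    audit: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Declarative run configuration.

    ``exposures`` maps trait_id -> summary TSV path; ``manifest`` maps
    trait_id -> trait kind.  Thresholds default to the study values:
    p < 1e-5 for taxa (5e-5 for metabolites), clumping r² 0.001 within
    10,000 kb, F >= 10, MAF >= 0.01, outcome-association p < 0.05,
    Bonferroni per level at alpha 0.05.
    """

    exposures: dict[str, str | Path] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)
    outcome: str | Path | None = None
    ld_table: str | Path | None = None
    blacklist: str | Path | None = None
    p_threshold: float = 1e-5
    p_threshold_metabolite: float = 5e-5
    p_threshold_reverse: float = 5e-8
    r2_max: float = 0.001
    window_kb: int = 10_000
    f_min: float = 10.0
    eaf_min: float = 0.01
    outcome_p_cut: float = 0.05
    palindrome_eaf_window: float = 0.08
    ivw_re_mode: str = "multiplicative"
    scheme: BonferroniScheme = field(default_factory=BonferroniScheme)
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        if "scheme" in raw and not isinstance(raw["scheme"], BonferroniScheme):
            s = raw["scheme"]
            raw["scheme"] = BonferroniScheme(
                m=dict(s.get("m", DEFAULT_TEST_COUNTS)),
                alpha=float(s.get("alpha", 0.05)),
            )
        return cls(**raw)


def analyze_pair(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDTable,
    config: PipelineConfig,
    p_threshold: float,
    blacklist: set[str] = frozenset(),
) -> ClassifiedResult:
    """Screen, harmonize, estimate, diagnose and classify one pair."""
    result = ClassifiedResult(
        trait_id=exposure.trait_id, trait_kind=exposure.trait_kind, primary=None
    )
    instr = select_instruments(
        exposure, outcome, ld,
        p_threshold=p_threshold, r2_max=config.r2_max,
        window_kb=config.window_kb, f_min=config.f_min,
        eaf_min=config.eaf_min, outcome_p_cut=config.outcome_p_cut,
        blacklist=blacklist,
    )
    result.audit = dict(instr.audit)
    selected = SummaryDataset(
        exposure.trait_id, exposure.trait_kind, instr.selected
    )
    hs = harmonize(selected, outcome, config.palindrome_eaf_window)
    result.n_instruments = len(hs)
    if not hs:
        result.failure = "no instruments"
        return result

    if len(hs) == 1:
        result.primary = est.wald_ratio(hs[0])
        result.estimates = {"wald": result.primary}
    else:
        result.primary = est.ivw(hs, re_mode=config.ivw_re_mode)
        result.estimates = {"ivw": result.primary}
        if len(hs) >= 3:
            result.estimates["egger"] = est.egger(hs)
            result.estimates["weighted_median"] = est.weighted_median(
                hs, n_boot=config.n_boot, seed=config.seed
            )
            result.estimates["weighted_mode"] = est.weighted_mode(
                hs, n_boot=config.n_boot, seed=config.seed
            )
        if len(hs) >= 2:
            result.sensitivity = sensitivity_report(
                hs, n_sim=config.presso_n_sim, seed=config.seed,
                alpha=config.scheme.alpha,
            )

    try:
        threshold = bonferroni_threshold(config.scheme, exposure.trait_kind)
    except KeyError:
        threshold = config.scheme.alpha  # unscheduled kinds: alpha only
    result.verdict = classify(result.primary, threshold, config.scheme.alpha)
    return result


def _load_inputs(config: PipelineConfig):
    outcome = read_summary_table(config.outcome, trait_kind="disease")
    ld = LDTable.read_tsv(config.ld_table) if config.ld_table else LDTable()
    blacklist = read_blacklist(config.blacklist) if config.blacklist else set()
    return outcome, ld, blacklist


def run_pipeline(
    config: PipelineConfig,
    datasets: Sequence[SummaryDataset] | None = None,
    outcome: SummaryDataset | None = None,
    ld: LDTable | None = None,
    blacklist: set[str] = frozenset(),
) -> list[ClassifiedResult]:
    """Forward MR for every configured exposure against the outcome.

    Inputs may be passed in memory (``datasets``/``outcome``/``ld``) or read
    from the files named in the config.  An exposure that loses all its
    instruments is recorded as a failure, never raised.
    """
    if outcome is None:
        outcome, ld, blacklist = _load_inputs(config)
        datasets = [
            read_summary_table(
                path, trait_id=tid,
                trait_kind=config.manifest.get(tid, "genus"),
            )
            for tid, path in config.exposures.items()
        ]
    ld = ld if ld is not None else LDTable()

    results = []
    for ds in datasets:
        p_thr = (config.p_threshold_metabolite
                 if ds.trait_kind == "metabolite" else config.p_threshold)
        results.append(
            analyze_pair(ds, outcome, ld, config, p_thr, blacklist)
        )
    return results


def run_reverse(
    config: PipelineConfig,
    disease: SummaryDataset | None = None,
    targets: Sequence[SummaryDataset] | None = None,
    ld: LDTable | None = None,
    blacklist: set[str] = frozenset(),
) -> list[ClassifiedResult]:
    """Reverse MR: the disease as exposure against each original exposure.

    Instrument selection runs on the disease summary statistics at
    ``config.p_threshold_reverse`` (genome-wide by default).
    """
    if disease is None:
        disease_all, ld, blacklist = _load_inputs(config)
        disease = disease_all
        targets = [
            read_summary_table(
                path, trait_id=tid,
                trait_kind=config.manifest.get(tid, "genus"),
            )
            for tid, path in config.exposures.items()
        ]
    ld = ld if ld is not None else LDTable()

    results = []
    for target in targets:
        res = analyze_pair(
            disease, target, ld, config, config.p_threshold_reverse, blacklist
        )
        # label the pair by its target so reverse rows are distinguishable
        res.trait_id = f"{disease.trait_id}->{target.trait_id}"
        res.trait_kind = target.trait_kind
        results.append(res)
    return results


def results_table(results: Sequence[ClassifiedResult]) -> pd.DataFrame:
    """Long-format results table: one row per exposure and method."""
    rows = []
    for r in results:
        if r.failure:
            rows.append({
                "exposure": r.trait_id, "level": r.trait_kind, "method": "",
                "n_snps": 0, "or": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan"), "pvalue": float("nan"),
                "verdict": r.failure,
            })
            continue
        for method, e in r.estimates.items():
            rows.append({
                "exposure": r.trait_id, "level": r.trait_kind,
                "method": method, "n_snps": e.n_snps, "or": e.or_,
                "ci_low": e.ci_low, "ci_high": e.ci_high, "pvalue": e.pvalue,
                "verdict": r.verdict if method == r.primary.method else "",
            })
    return pd.DataFrame(rows, columns=[
        "exposure", "level", "method", "n_snps", "or", "ci_low", "ci_high",
        "pvalue", "verdict",
    ])


def forest_table(results: Sequence[ClassifiedResult]) -> pd.DataFrame:
    """Forest-plot table of the primary (IVW) estimates only."""
    rows = []
    for r in results:
        if r.failure or r.primary is None:
            continue
        rows.append({
            "exposure": r.trait_id, "level": r.trait_kind,
            "n_snps": r.primary.n_snps, "or": r.primary.or_,
            "ci_low": r.primary.ci_low, "ci_high": r.primary.ci_high,
            "pvalue": r.primary.pvalue, "verdict": r.verdict,
        })
    return pd.DataFrame(rows, columns=[
        "exposure", "level", "n_snps", "or", "ci_low", "ci_high", "pvalue",
        "verdict",
    ])
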