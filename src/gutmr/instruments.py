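"""Instrumental-variable screening for two-sample MR.

The screen mirrors the standard MR workflow for microbiome exposures:
locus-wide significance (p < 1e-5, relaxed to 5e-5 for metabolites), greedy
LD clumping (r² < 0.001 within 10,000 kb), per-instrument strength (F >= 10
from R² = 2·EAF·(1−EAF)·β²), a minor-allele-frequency floor (0.01), removal
of variants directly associated with the outcome (p < 0.05), and a static
confounder blacklist standing in for a Phenoscanner lookup.

Every candidate that is removed is recorded in an audit trail, so that the
retained set plus the audited exclusions always reconstructs the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from gutmr.sumstats import SummaryDataset, VariantAssociation


class DegenerateInputError(ValueError):
    """Raised when a formula is evaluated outside its domain."""


@dataclass
class LDTable:
    """Pairwise linkage-disequilibrium (r²) lookup.

    Pairs are unordered; a missing pair is treated as r² = 0 and the
    diagonal is always 1.
    """

    _r2: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "LDTable":
        table = cls()
        for a, b, r2 in pairs:
            table.set(a, b, r2)
        return table

    @classmethod
    def read_tsv(cls, path: str | Path) -> "LDTable":
        """Read a TSV with columns variant_a, variant_b, r2."""
        df = pd.read_csv(path, sep="\t")
        return cls.from_pairs(
            zip(df["variant_a"].astype(str), df["variant_b"].astype(str),
                df["r2"].astype(float))
        )

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 must be in [0,1], got {r2}")
        self._r2[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def has_pair(self, a: str, b: str) -> bool:
        return a == b or frozenset((a, b)) in self._r2

    def __len__(self) -> int:
        return len(self._r2)


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure plus the exclusion audit."""

    trait_id: str
    selected: list[VariantAssociation] = field(default_factory=list)
    r2_explained: dict[str, float] = field(default_factory=dict)
    f_stat: dict[str, float] = field(default_factory=dict)
    audit: dict[str, str] = field(default_factory=dict)  # variant_id -> reason

    def record_exclusions(self, before: SummaryDataset, after: SummaryDataset,
                          reason: str) -> None:
        kept = {r.variant_id for r in after.records}
        for r in before.records:
            if r.variant_id not in kept:
                self.audit[r.variant_id] = reason


def select_by_pvalue(ds: SummaryDataset, threshold: float) -> SummaryDataset:
    """Keep variants with association p-value strictly below ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    return SummaryDataset(
        ds.trait_id, ds.trait_kind,
        [r for r in ds.records if r.pvalue < threshold],
    )


def greedy_ld_clump(
    candidates: SummaryDataset,
    ld: LDTable,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
) -> SummaryDataset:
    """Greedy LD clumping: keep the most significant variant, discard its
    neighbours, repeat.

    A neighbour is discarded when its r² with the kept index variant exceeds
    ``r2_max``, or — when the pair is absent from the LD table — when it lies
    within ``window_kb`` of the index on the same chromosome (distance-based
    fallback).  Ties on p-value break lexicographically on ``variant_id`` so
    the result is deterministic.
    """
    ordered = sorted(candidates.records, key=lambda r: (r.pvalue, r.variant_id))
    kept: list[VariantAssociation] = []
    removed: set[str] = set()
    for idx_var in ordered:
        if idx_var.variant_id in removed:
            continue
        kept.append(idx_var)
        for other in ordered:
            if other.variant_id == idx_var.variant_id or other.variant_id in removed:
                continue
            if ld.has_pair(idx_var.variant_id, other.variant_id):
                if ld.r2(idx_var.variant_id, other.variant_id) > r2_max:
                    removed.add(other.variant_id)
            elif (
                idx_var.chrom is not None
                and idx_var.chrom == other.chrom
                and idx_var.pos is not None
                and other.pos is not None
                and abs(idx_var.pos - other.pos) <= window_kb * 1000
            ):
                removed.add(other.variant_id)
    kept_ids = {r.variant_id for r in kept}
    return candidates.subset(kept_ids)


def instrument_strength(v: VariantAssociation, k: int = 1) -> tuple[float, float]:
    """Variance explained and F-statistic of one instrument.

    R² = 2·EAF·(1−EAF)·β² on the standardized-trait scale;
    F = (R²/(1−R²))·((N−K−1)/K) with K instruments and N samples.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    r2 = 2.0 * v.eaf * (1.0 - v.eaf) * v.beta ** 2
    if r2 >= 1.0:
        raise DegenerateInputError(
            f"{v.variant_id}: variance explained {r2:.3f} >= 1"
        )
    f = (r2 / (1.0 - r2)) * ((v.n - k - 1) / k)
    return r2, f


def filter_weak(
    instr: InstrumentSet, ds: SummaryDataset, f_min: float = 10.0, k: int = 1
) -> SummaryDataset:
    """Drop instruments with F below ``f_min``; strength stored on the set."""
    kept = []
    for v in ds.records:
        r2, f = instrument_strength(v, k=k)
        instr.r2_explained[v.variant_id] = r2
        instr.f_stat[v.variant_id] = f
        if f >= f_min:
            kept.append(v)
        else:
            instr.audit[v.variant_id] = f"weak instrument (F={f:.2f} < {f_min})"
    return SummaryDataset(ds.trait_id, ds.trait_kind, kept)


def filter_eaf(
    ds: SummaryDataset, eaf_min: float = 0.01, symmetric: bool = True
) -> SummaryDataset:
    """Drop rare variants.

    With ``symmetric=True`` (default) the floor applies to the minor-allele
    frequency, i.e. both eaf and 1−eaf must be at least ``eaf_min``; with
    ``symmetric=False`` only the effect-allele frequency is checked.
    """
    def ok(r: VariantAssociation) -> bool:
        if symmetric:
            return r.eaf >= eaf_min and (1.0 - r.eaf) >= eaf_min
        return r.eaf >= eaf_min

    return SummaryDataset(ds.trait_id, ds.trait_kind,
                          [r for r in ds.records if ok(r)])


def exclude_outcome_associated(
    ds: SummaryDataset, outcome: SummaryDataset, p_cut: float = 0.05
) -> SummaryDataset:
    """Drop instruments directly associated with the outcome (p < ``p_cut``).

    Variants absent from the outcome dataset are kept (they cannot be tested
    here; the overlap check happens again at harmonization).
    """
    out_by_id = outcome.by_id()
    kept = []
    for r in ds.records:
        out = out_by_id.get(r.variant_id)
        if out is not None and out.pvalue < p_cut:
            continue
        kept.append(r)
    return SummaryDataset(ds.trait_id, ds.trait_kind, kept)


def apply_blacklist(ds: SummaryDataset, blacklist: Iterable[str]) -> SummaryDataset:
    """Remove variants on a confounder blacklist (static Phenoscanner stand-in)."""
    blacklist = set(blacklist)
    return SummaryDataset(
        ds.trait_id, ds.trait_kind,
        [r for r in ds.records if r.variant_id not in blacklist],
    )


def read_blacklist(path: str | Path) -> set[str]:
    """One variant_id per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDTable,
    p_threshold: float = 1e-5,
    r2_max: float = 0.001,
    window_kb: int = 10_000,
    f_min: float = 10.0,
    eaf_min: float = 0.01,
    outcome_p_cut: float = 0.05,
    blacklist: Iterable[str] = (),
) -> InstrumentSet:
    """Run the full screening cascade and return the audited instrument set."""
    instr = InstrumentSet(trait_id=exposure.trait_id)

    stage = select_by_pvalue(exposure, p_threshold)
    instr.record_exclusions(exposure, stage, f"p >= {p_threshold}")

    clumped = greedy_ld_clump(stage, ld, r2_max=r2_max, window_kb=window_kb)
    instr.record_exclusions(stage, clumped, "LD clumped")

    strong = filter_weak(instr, clumped, f_min=f_min)

    frequent = filter_eaf(strong, eaf_min=eaf_min)
    instr.record_exclusions(strong, frequent, f"MAF < {eaf_min}")

    unconfounded = exclude_outcome_associated(frequent, outcome, p_cut=outcome_p_cut)
    instr.record_exclusions(frequent, unconfounded,
                            f"outcome-associated (p < {outcome_p_cut})")

    final = apply_blacklist(unconfounded, blacklist)
    instr.record_exclusions(unconfounded, final, "confounder blacklist")

    instr.selected = list(final.records)
    return instr
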