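"""GWAS summary-statistic data model, TSV I/O and allele harmonization.

A summary-statistic file is a tab-separated table with one row per variant.
The canonical header is ``variant_id  chrom  pos  effect_allele  other_allele
eaf  beta  se  pvalue  n``; files using other column names are read through a
``column_map``.  Harmonization aligns exposure and outcome effects onto the
shared effect allele and attaches the per-variant Wald ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: complement map used to recognise strand flips and palindromic variants
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order for summary-statistic TSV files
CANONICAL_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
)

TRAIT_KINDS = frozenset(
    {"genus", "family", "order", "class", "phylum", "metabolite", "disease"}
)


class SumstatsError(ValueError):
    """Configuration or contract violation in summary-statistic handling."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association summary statistics for a single trait.

    ``beta`` is the effect per copy of ``effect_allele`` (log odds for binary
    traits); ``eaf`` is the effect-allele frequency.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise SumstatsError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise SumstatsError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise SumstatsError("effect and other allele must differ")
        if not 0.0 < self.eaf < 1.0:
            raise SumstatsError(f"eaf must be in (0,1), got {self.eaf}")
        if not self.se > 0.0:
            raise SumstatsError(f"se must be > 0, got {self.se}")
        if not 0.0 < self.pvalue <= 1.0:
            raise SumstatsError(f"pvalue must be in (0,1], got {self.pvalue}")
        if not self.n > 0:
            raise SumstatsError(f"n must be > 0, got {self.n}")
        if self.pos is not None and self.pos < 1:
            raise SumstatsError(f"pos must be >= 1, got {self.pos}")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants (ambiguous across strands)."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SummaryDataset:
    """A set of variant associations for one trait."""

    trait_id: str
    trait_kind: str
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_kind not in TRAIT_KINDS:
            raise SumstatsError(f"unknown trait_kind {self.trait_kind!r}")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise SumstatsError(f"duplicate variant_id in dataset {self.trait_id!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_id(self) -> dict[str, VariantAssociation]:
        return {r.variant_id: r for r in self.records}

    def subset(self, keep: Iterable[str]) -> "SummaryDataset":
        """New dataset restricted to the given variant ids (input order kept)."""
        keep = set(keep)
        return SummaryDataset(
            self.trait_id, self.trait_kind,
            [r for r in self.records if r.variant_id in keep],
        )


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects aligned to a shared effect allele.

    ``ratio`` is the Wald ratio beta_out/beta_exp; ``ratio_se`` its first-order
    delta-method standard error se_out/|beta_exp|.
    """

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float

    def __post_init__(self) -> None:
        if self.beta_exp == 0.0:
            raise SumstatsError("beta_exp must be nonzero for an instrument")
        if self.se_out <= 0.0 or self.se_exp <= 0.0:
            raise SumstatsError("standard errors must be positive")

    @property
    def ratio(self) -> float:
        return self.beta_out / self.beta_exp

    @property
    def ratio_se(self) -> float:
        return self.se_out / abs(self.beta_exp)


def _coerce_row(row: Mapping[str, object], line_no: int) -> VariantAssociation:
    def opt(key, cast):
        v = row.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return cast(v)

    return VariantAssociation(
        variant_id=str(row["variant_id"]),
        effect_allele=str(row["effect_allele"]).upper(),
        other_allele=str(row["other_allele"]).upper(),
        eaf=float(row["eaf"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        pvalue=float(row["pvalue"]),
        n=int(float(row["n"])),
        chrom=opt("chrom", str),
        pos=opt("pos", lambda v: int(float(v))),
    )


def read_summary_table(
    path: str | Path,
    trait_id: str | None = None,
    trait_kind: str = "genus",
    column_map: Mapping[str, str] | None = None,
) -> SummaryDataset:
    """Read a tab-separated summary-statistic table.

    Parameters
    ----------
    path
        TSV file with a header line.
    trait_id
        Trait label; defaults to the file stem.
    trait_kind
        One of genus/family/order/class/phylum/metabolite/disease.
    column_map
        Mapping from canonical name to the column name used in the file,
        e.g. ``{"variant_id": "SNP", "pvalue": "P"}``.  Unmapped canonical
        names are looked up verbatim.

    Rows violating the type invariants (se <= 0, eaf outside (0,1), equal
    alleles, ...) are rejected and logged with their line number; the valid
    rows are kept.

    Raises
    ------
    SumstatsError
        If a required mapped column is missing from the file.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype=str)
    rename = {column_map.get(c, c): c for c in CANONICAL_COLUMNS}
    required = [c for c in CANONICAL_COLUMNS if c not in ("chrom", "pos")]
    present = {src: dst for src, dst in rename.items() if src in df.columns}
    df = df.rename(columns=present)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsError(f"{path}: missing required column(s) {missing}")

    records: list[VariantAssociation] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        line_no = idx + 2  # 1-based, after the header
        try:
            records.append(_coerce_row(row, line_no))
        except (SumstatsError, ValueError, KeyError) as exc:
            logger.warning("%s line %d: row rejected (%s)", path, line_no, exc)
    return SummaryDataset(
        trait_id=trait_id or path.stem, trait_kind=trait_kind, records=records
    )


def write_summary_table(ds: SummaryDataset, path: str | Path) -> None:
    """Write a dataset as a canonical tab-separated table.

    Values are printed at full ``repr`` precision so that
    :func:`read_summary_table` inverts the file exactly.
    """
    rows = [
        {
            "variant_id": r.variant_id,
            "chrom": r.chrom if r.chrom is not None else "",
            "pos": r.pos if r.pos is not None else "",
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": repr(r.eaf),
            "beta": repr(r.beta),
            "se": repr(r.se),
            "pvalue": repr(r.pvalue),
            "n": r.n,
        }
        for r in ds.records
    ]
    df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonizedInstrument]:
    """Align outcome effects onto the exposure effect allele.

    For each variant present in both datasets:

    * identical allele coding → outcome effect kept as-is;
    * effect/other alleles swapped in the outcome (directly or on the
      opposite strand) → outcome beta negated, outcome EAF reflected;
    * any other allele combination → dropped as inconsistent;
    * palindromic variants (A/T, C/G) whose exposure EAF lies within
      ``palindrome_eaf_window`` of 0.5 → dropped as strand-ambiguous.

    Instruments with a zero exposure effect are dropped (no Wald ratio).
    Returns the harmonized instruments in exposure order; an empty overlap
    is reported with a warning since it usually signals mismatched inputs.
    """
    out_by_id = outcome.by_id()
    shared = [r for r in exposure.records if r.variant_id in out_by_id]
    if not shared:
        logger.warning(
            "no shared variants between %s and %s — check variant id dialects",
            exposure.trait_id, outcome.trait_id,
        )
        return []

    harmonized: list[HarmonizedInstrument] = []
    for ex in shared:
        if ex.beta == 0.0:
            continue  # no Wald ratio without an exposure effect
        out = out_by_id[ex.variant_id]
        if ex.is_palindromic:
            if abs(ex.eaf - 0.5) <= palindrome_eaf_window:
                continue  # strand-ambiguous at intermediate frequency
            # outside the window the allele letters determine orientation
        pair = (out.effect_allele, out.other_allele)
        flipped_pair = (
            _COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele]
        )
        if pair == (ex.effect_allele, ex.other_allele):
            beta_out = out.beta
        elif pair == (ex.other_allele, ex.effect_allele):
            beta_out = -out.beta
        elif not ex.is_palindromic and flipped_pair == (
            ex.effect_allele, ex.other_allele
        ):
            beta_out = out.beta  # same orientation, opposite strand
        elif not ex.is_palindromic and flipped_pair == (
            ex.other_allele, ex.effect_allele
        ):
            beta_out = -out.beta
        else:
            continue  # inconsistent alleles
        harmonized.append(
            HarmonizedInstrument(
                variant_id=ex.variant_id,
                beta_exp=ex.beta,
                se_exp=ex.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf_exp=ex.eaf,
            )
        )
    return harmonized
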