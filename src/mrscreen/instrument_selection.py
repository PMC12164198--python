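"""Instrumental-variable selection from exposure summary statistics.

The selection chain is: association p-value filter, greedy LD clumping
(r-squared and distance window), weak-instrument F filter, harmonization
against the outcome, and exclusion of outcome-associated variants.  All
threshold comparisons are strict: a record is removed when p < threshold or
F < f_min, and retained at equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from mrscreen.sumstats_io import (
    GwasRecord,
    HarmonizedSet,
    SummaryDataset,
    SumstatsError,
    harmonize,
)

logger = logging.getLogger(__name__)


class LdSource:
    """Pairwise LD (r-squared) lookup between variant ids.

    Pairs absent from the source are treated as r² = 0; the relation is
    stored symmetrically.  LD is taken as given input — the package never
    computes it from genotypes.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self.add(a, b, r2)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of range for pair ({a}, {b}): {r2}")
        if a != b:
            self._r2[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_table(cls, path: str | Path) -> "LdSource":
        """Read a pairwise TSV with headers ``snp_id_1 snp_id_2 r2``."""
        df = pd.read_csv(path, sep="\t", dtype={"snp_id_1": str, "snp_id_2": str})
        for col in ("snp_id_1", "snp_id_2", "r2"):
            if col not in df.columns:
                raise SumstatsError(f"LD table missing column {col!r}")
        src = cls()
        for a, b, r2 in df[["snp_id_1", "snp_id_2", "r2"]].itertuples(index=False):
            src.add(str(a), str(b), float(r2))
        return src

    @classmethod
    def from_matrix(cls, matrix, variant_ids) -> "LdSource":
        """Build from a square r² matrix (rows/cols follow variant_ids)."""
        src = cls()
        ids = list(variant_ids)
        for i, a in enumerate(ids):
            for j in range(i + 1, len(ids)):
                src.add(a, ids[j], float(matrix[i][j]))
        return src


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure plus the selection audit trail."""

    exposure_id: str
    variants: list[GwasRecord]
    f_statistics: dict[str, float] = field(default_factory=dict)
    selection_log: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variants)


def filter_pvalue(ds: SummaryDataset, threshold: float = 1e-5) -> SummaryDataset:
    """Keep records associated with the exposure at p < threshold (strict)."""
    kept = [r for r in ds.records if r.pval < threshold]
    if not kept:
        logger.info("p-value filter left no records for %s", ds.trait_id)
    return replace(ds, records=kept)


def clump(
    ds: SummaryDataset,
    ld: LdSource,
    r2_max: float = 0.1,
    window_kb: int = 500,
) -> SummaryDataset:
    """Greedy LD clumping.

    Repeatedly take the remaining record with the smallest p-value (ties
    broken by variant_id) as the index, retain it, and drop every remaining
    record with r² > r2_max to the index that lies within ±window_kb on the
    same chromosome.  The retained set is independent of input order.
    """
    remaining = sorted(ds.records, key=lambda r: (r.pval, r.variant_id))
    window_bp = window_kb * 1000
    kept: list[GwasRecord] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        remaining = [
            r
            for r in remaining
            if not (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window_bp
                and ld.r2(index.variant_id, r.variant_id) > r2_max
            )
        ]
    kept_ids = {r.variant_id for r in kept}
    return replace(ds, records=[r for r in ds.records if r.variant_id in kept_ids])


def f_statistic(record: GwasRecord) -> float:
    """Single-SNP instrument-strength F statistic, (beta/se)²."""
    return (record.beta / record.se) ** 2


def filter_weak(ds: SummaryDataset, f_min: float = 10.0) -> SummaryDataset:
    """Exclude weak instruments with F < f_min (strict; F = f_min is kept)."""
    kept = [r for r in ds.records if f_statistic(r) >= f_min]
    if len(kept) < len(ds.records):
        logger.info(
            "excluded %d weak instrument(s) (F < %g) for %s",
            len(ds.records) - len(kept),
            f_min,
            ds.trait_id,
        )
    return replace(ds, records=kept)


def exclude_outcome_associated(
    hs: HarmonizedSet, threshold: float = 1e-5
) -> HarmonizedSet:
    """Remove variants associated with the outcome at p < threshold."""
    kept = [v for v in hs.variants if not v.pval_out < threshold]
    if not kept:
        logger.info(
            "all instruments of %s are outcome-associated", hs.exposure_id
        )
    return HarmonizedSet(
        exposure_id=hs.exposure_id,
        outcome_id=hs.outcome_id,
        variants=kept,
        n_exposure=hs.n_exposure,
        n_outcome=hs.n_outcome,
    )


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LdSource,
    pval_threshold: float = 1e-5,
    r2_max: float = 0.1,
    window_kb: int = 500,
    f_min: float = 10.0,
    outcome_pval_threshold: float = 1e-5,
    palindrome_policy: str = "drop_ambiguous",
) -> tuple[HarmonizedSet | None, InstrumentSet]:
    """Run the full selection chain for one exposure.

    Order: p-filter → clump → F-filter → harmonize → outcome-association
    exclusion.  Returns the harmonized instrument set (None when nothing
    survives) together with an InstrumentSet carrying per-stage counts.
    """
    log: dict[str, int] = {"input": len(exposure)}
    ds = filter_pvalue(exposure, pval_threshold)
    log["after_pvalue_filter"] = len(ds)
    ds = clump(ds, ld, r2_max=r2_max, window_kb=window_kb)
    log["after_clump"] = len(ds)
    fstats = {r.variant_id: f_statistic(r) for r in ds.records}
    ds = filter_weak(ds, f_min)
    log["after_f_filter"] = len(ds)

    hs: HarmonizedSet | None = None
    if len(ds) > 0:
        try:
            hs = harmonize(ds, outcome, palindrome_policy=palindrome_policy)
        except SumstatsError:
            hs = None
    log["after_harmonize"] = 0 if hs is None else len(hs)
    if hs is not None:
        hs = exclude_outcome_associated(hs, outcome_pval_threshold)
        if len(hs) == 0:
            hs = None
    log["after_outcome_exclusion"] = 0 if hs is None else len(hs)

    kept_ids = set() if hs is None else {v.variant_id for v in hs.variants}
    inst = InstrumentSet(
        exposure_id=exposure.trait_id,
        variants=[r for r in ds.records if r.variant_id in kept_ids],
        f_statistics={k: v for k, v in fstats.items() if k in kept_ids},
        selection_log=log,
    )
    return hs, inst
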