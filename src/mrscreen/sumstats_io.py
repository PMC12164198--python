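"""Reading, validation and harmonization of GWAS summary statistics.

Summary statistics are exchanged as tab-delimited tables with one row per
variant.  The default dialect uses the headers::

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

Effect sizes for binary traits are on the log-odds scale.  Harmonization
aligns exposure and outcome effects to the exposure's effect allele, handling
allele swaps, strand complementation and palindromic (A/T, G/C) variants.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: GwasRecord fields that must be mapped when reading a summary file.
REQUIRED_FIELDS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
)
OPTIONAL_FIELDS = ("eaf", "n")

#: Default file header for each record field (the package's TSV dialect).
DEFAULT_HEADERS = {
    "snp_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}


class SumstatsError(ValueError):
    """Raised for unreadable or structurally invalid summary statistics."""


@dataclass(frozen=True)
class GwasRecord:
    """One variant's association summary for a single trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for a
    binary trait); ``eaf`` and ``n`` may be missing (``None``).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None = None

    def is_valid(self) -> bool:
        """Check the record invariants without raising."""
        if self.effect_allele not in VALID_ALLELES:
            return False
        if self.other_allele not in VALID_ALLELES:
            return False
        if self.effect_allele == self.other_allele:
            return False
        if not (self.se > 0 and math.isfinite(self.se)):
            return False
        if not (0 < self.pval <= 1):
            return False
        if not math.isfinite(self.beta):
            return False
        if self.eaf is not None and not (0 < self.eaf < 1):
            return False
        if self.n is not None and self.n <= 0:
            return False
        return True

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass
class SummaryDataset:
    """A full summary-statistics table for one trait."""

    trait_id: str
    records: list[GwasRecord]
    trait_label: str = ""
    category: str = ""
    sample_size: int | None = None

    def __post_init__(self) -> None:
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise SumstatsError(
                f"duplicate variant_id in dataset {self.trait_id!r}"
            )
        if not self.trait_label:
            self.trait_label = self.trait_id

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, GwasRecord]:
        return {r.variant_id: r for r in self.records}

    def subset(self, variant_ids: Iterable[str]) -> "SummaryDataset":
        keep = set(variant_ids)
        return replace(
            self, records=[r for r in self.records if r.variant_id in keep]
        )


@dataclass(frozen=True)
class HarmonizedVariant:
    """Exposure and outcome effects aligned to the same effect allele."""

    variant_id: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    beta_out: float
    se_out: float
    pval_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None


@dataclass
class HarmonizedSet:
    """The per-variant (beta_exp, beta_out) pairs every estimator consumes."""

    exposure_id: str
    outcome_id: str
    variants: list[HarmonizedVariant]
    n_exposure: int | None = None
    n_outcome: int | None = None

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(ids) != len(set(ids)):
            raise SumstatsError("duplicate variant_id in harmonized set")

    def __len__(self) -> int:
        return len(self.variants)

    def arrays(self):
        """Return (beta_exp, se_exp, beta_out, se_out) as numpy arrays."""
        import numpy as np

        bx = np.array([v.beta_exp for v in self.variants], dtype=float)
        sx = np.array([v.se_exp for v in self.variants], dtype=float)
        by = np.array([v.beta_out for v in self.variants], dtype=float)
        sy = np.array([v.se_out for v in self.variants], dtype=float)
        return bx, sx, by, sy

    def subset_indices(self, indices: Sequence[int]) -> "HarmonizedSet":
        return HarmonizedSet(
            exposure_id=self.exposure_id,
            outcome_id=self.outcome_id,
            variants=[self.variants[i] for i in indices],
            n_exposure=self.n_exposure,
            n_outcome=self.n_outcome,
        )


def _coerce_record(row: Mapping[str, object]) -> GwasRecord | None:
    try:
        eaf = row.get("eaf")
        n = row.get("n")
        rec = GwasRecord(
            variant_id=str(row["variant_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            eaf=None if eaf is None or pd.isna(eaf) else float(eaf),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            n=None if n is None or pd.isna(n) else int(n),
        )
    except (KeyError, TypeError, ValueError):
        return None
    return rec if rec.is_valid() else None


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_label: str = "",
    category: str = "",
    sample_size: int | None = None,
) -> SummaryDataset:
    """Read a tab-delimited summary-statistics file into a SummaryDataset.

    Parameters
    ----------
    path
        Tab-delimited file with a header row.
    column_map
        Mapping from file headers to record fields (``variant_id``, ``chrom``,
        ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``,
        ``se``, ``pval``, ``n``).  Defaults to the package dialect.
    trait_id
        Identifier for the trait; defaults to the file stem.

    Rows violating the record invariants (non-positive SE, p outside (0, 1],
    identical alleles, ...) are dropped with a logged count.  A missing mapped
    column or zero valid rows is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise SumstatsError(f"no such file: {path}")
    column_map = dict(column_map) if column_map is not None else dict(DEFAULT_HEADERS)

    mapped_fields = set(column_map.values())
    for fld in REQUIRED_FIELDS:
        if fld not in mapped_fields:
            raise SumstatsError(f"column_map does not provide field {fld!r}")

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [h for h in column_map if h not in df.columns]
    # optional fields may be absent from the file entirely
    hard_missing = [h for h in missing if column_map[h] in REQUIRED_FIELDS]
    if hard_missing:
        raise SumstatsError(
            f"missing mapped column(s) {hard_missing!r} in {path}"
        )
    for h in missing:
        column_map.pop(h)

    df = df[list(column_map)].rename(columns=column_map)
    records: list[GwasRecord] = []
    n_dropped = 0
    for row in df.to_dict("records"):
        rec = _coerce_record(row)
        if rec is None:
            n_dropped += 1
        else:
            records.append(rec)
    if n_dropped:
        logger.warning("dropped %d invalid row(s) from %s", n_dropped, path)
    if not records:
        raise SumstatsError(f"no valid rows in {path}")

    ds = SummaryDataset(
        trait_id=trait_id or path.stem,
        trait_label=trait_label,
        category=category,
        records=records,
        sample_size=sample_size,
    )
    return ds


def _align_outcome(
    exp: GwasRecord, out: GwasRecord
) -> tuple[float, float | None] | None:
    """Return (sign, eaf_out) aligning a non-palindromic outcome record to the
    exposure's effect allele, or None when the allele pairs are incompatible.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    pairs = {
        (out.effect_allele, out.other_allele): 1.0,
        (out.other_allele, out.effect_allele): -1.0,
        (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele]): 1.0,
        (COMPLEMENT[out.other_allele], COMPLEMENT[out.effect_allele]): -1.0,
    }
    sign = pairs.get((ea, oa))
    if sign is None:
        return None
    if out.eaf is None:
        eaf = None
    else:
        eaf = out.eaf if sign > 0 else 1.0 - out.eaf
    return sign, eaf


def _align_palindromic(
    exp: GwasRecord,
    out: GwasRecord,
    policy: str,
    band: tuple[float, float],
) -> tuple[float, float | None] | None:
    if not exp.is_palindromic or {exp.effect_allele, exp.other_allele} != {
        out.effect_allele,
        out.other_allele,
    }:
        return None  # incompatible allele pair
    if policy == "drop_ambiguous":
        return None
    # infer_by_eaf: keep only when both frequencies sit outside the ambiguity
    # band; same side of 0.5 -> same orientation, opposite sides -> flip.
    if exp.eaf is None or out.eaf is None:
        return None
    lo, hi = band
    if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
        return None
    if (exp.eaf < 0.5) == (out.eaf < 0.5):
        return 1.0, out.eaf
    return -1.0, 1.0 - out.eaf


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindrome_policy: str = "drop_ambiguous",
    eaf_ambiguity_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome effects to each exposure variant's effect allele.

    Variants present in both datasets are aligned: swapped alleles negate the
    outcome beta (and reflect its eaf), strand-complemented alleles are
    matched after complementation, and palindromic variants are handled per
    ``palindrome_policy`` (``drop_ambiguous`` removes them all;
    ``infer_by_eaf`` orients by allele frequency outside the ambiguity band).
    Incompatible allele pairs are dropped.  An empty result is a hard error.
    """
    if palindrome_policy not in ("drop_ambiguous", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    out_by_id = outcome.by_id()
    variants: list[HarmonizedVariant] = []
    for exp in exposure.records:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            continue
        if exp.is_palindromic or out.is_palindromic:
            aligned = _align_palindromic(
                exp, out, palindrome_policy, eaf_ambiguity_band
            )
        else:
            aligned = _align_outcome(exp, out)
        if aligned is None:
            continue
        sign, eaf_out = aligned
        variants.append(
            HarmonizedVariant(
                variant_id=exp.variant_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                pval_exp=exp.pval,
                beta_out=sign * out.beta,
                se_out=out.se,
                pval_out=out.pval,
                eaf_exp=exp.eaf,
                eaf_out=eaf_out,
            )
        )
    if not variants:
        raise SumstatsError(
            f"no variant could be harmonized between {exposure.trait_id!r} "
            f"and {outcome.trait_id!r}"
        )
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        variants=variants,
        n_exposure=exposure.sample_size,
        n_outcome=outcome.sample_size,
    )


def _format_float(x: object) -> object:
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def write_results(
    report: pd.DataFrame | Sequence[Mapping[str, object]],
    path: str | Path,
    format: str = "tsv",
) -> Path:
    """Write a results table as TSV or JSON with stable 6-significant-digit
    float formatting; writing an empty report is an error."""
    if not isinstance(report, pd.DataFrame):
        report = pd.DataFrame(list(report))
    if report.empty:
        raise ValueError("refusing to write an empty report")
    path = Path(path)
    if format == "tsv":
        report.to_csv(path, sep="\t", index=False, float_format="%.6g")
    elif format == "json":
        rows = [
            {k: _format_float(v) for k, v in row.items()}
            for row in report.to_dict("records")
        ]
        path.write_text(json.dumps(rows, indent=1, default=str) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
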