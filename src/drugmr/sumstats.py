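"""GWAS summary-statistic data model, I/O and allele harmonization.

Coordinates are 1-based inclusive throughout (GWAS/VCF convention).
Variants are matched across datasets by variant identifier (rsID), not by
position.  Only biallelic single-nucleotide variants are retained: indels
and records failing basic invariants (``se > 0``, ``pval`` in (0, 1],
identical alleles, out-of-range frequency) are dropped at ingestion and
counted.

Harmonization aligns an outcome (or mediator) dataset to the exposure's
effect alleles: matching allele pairs are kept as-is, swapped pairs have
the outcome beta negated and the frequency mirrored, strand-complemented
pairs are complemented first, and palindromic variants (A/T or C/G, whose
strand cannot be resolved from allele labels) are always removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default header names for summary-statistic tables
DEFAULT_COLUMNS: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_REQUIRED_FIELDS = ("variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pval")
_OPTIONAL_FIELDS = ("eaf", "n")


class ColumnMappingError(KeyError):
    """A required column is absent from the input table."""


class EmptyInputError(ValueError):
    """The input table contains no data rows."""


class AlleleError(ValueError):
    """An allele code is outside {A, C, G, T}."""


class NoSharedVariantsError(ValueError):
    """Exposure and outcome share no variant identifiers."""


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele`` in trait
    units (quantitative traits) or log-odds (binary traits); ``eaf`` is the
    effect-allele frequency and may be ``None``, as may the sample size ``n``.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def validate(self) -> None:
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise AlleleError(f"{self.variant_id}: non-ACGT allele pair "
                              f"({self.effect_allele!r}, {self.other_allele!r})")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical alleles")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval must be in (0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1")


@dataclass(frozen=True)
class GeneRegion:
    """A gene's genomic span, 1-based and inclusive at both ends."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")

    @classmethod
    def from_string(cls, spec: str, gene: str = "") -> "GeneRegion":
        """Parse ``chr5:74632993-74657941`` style region strings."""
        chrom, _, span = spec.partition(":")
        lo, _, hi = span.partition("-")
        return cls(gene=gene or chrom, chrom=chrom, start=int(lo), end=int(hi))


@dataclass(frozen=True)
class HarmonizedRecord:
    """Exposure/outcome effects for one variant on a common effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float | None = None
    chrom: str = ""
    pos: int = 0


@dataclass
class HarmonizedSet:
    """Exposure/outcome records aligned to the exposure's effect alleles."""

    records: list[HarmonizedRecord]
    n_palindromic_removed: int = 0
    n_incompatible_removed: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "beta_exposure": [r.beta_exposure for r in self.records],
                "se_exposure": [r.se_exposure for r in self.records],
                "beta_outcome": [r.beta_outcome for r in self.records],
                "se_outcome": [r.se_outcome for r in self.records],
                "eaf": [r.eaf for r in self.records],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HarmonizedSet":
        df = pd.read_csv(path, sep="\t")
        records = [
            HarmonizedRecord(
                variant_id=str(row.variant_id),
                beta_exposure=float(row.beta_exposure),
                se_exposure=float(row.se_exposure),
                beta_outcome=float(row.beta_outcome),
                se_outcome=float(row.se_outcome),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                chrom=str(row.chrom),
                pos=int(row.pos),
            )
            for row in df.itertuples()
        ]
        return cls(records=records)


@dataclass
class IngestCounts:
    """Bookkeeping of rows dropped during ingestion, by reason."""

    n_read: int = 0
    n_kept: int = 0
    n_invalid: int = 0
    n_non_snp: int = 0
    by_reason: dict[str, int] = field(default_factory=dict)

    def _bump(self, reason: str) -> None:
        self.by_reason[reason] = self.by_reason.get(reason, 0) + 1


def _coerce_float(value) -> float | None:
    if value is None:
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(out) else out


def read_sumstats_counted(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> tuple[list[SummaryRecord], IngestCounts]:
    """Read a delimited summary-statistic table, returning records and drop counts.

    ``column_map`` maps field names (``variant_id``, ``beta``, ...) to the
    header names used in the file; unmapped fields fall back to the defaults
    in :data:`DEFAULT_COLUMNS`.  Tab- and comma-delimited files are
    auto-detected; gzip compression is transparent.  Rows violating record
    invariants, indels and non-ACGT alleles are dropped and counted.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)

    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", compression="infer")
    else:
        df = pd.read_csv(path, sep=sep, compression="infer")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")

    for fieldname in _REQUIRED_FIELDS:
        if colmap[fieldname] not in df.columns:
            raise ColumnMappingError(
                f"{path}: required column {colmap[fieldname]!r} (field {fieldname!r}) not found; "
                f"available: {list(df.columns)}"
            )

    counts = IngestCounts(n_read=len(df))
    records: list[SummaryRecord] = []
    has_eaf = colmap["eaf"] in df.columns
    has_n = colmap["n"] in df.columns
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        ea = str(row_d[colmap["effect_allele"]]).upper()
        oa = str(row_d[colmap["other_allele"]]).upper()
        if len(ea) != 1 or len(oa) != 1 or ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
            counts.n_non_snp += 1
            counts._bump("non_snp_allele")
            continue
        eaf = _coerce_float(row_d[colmap["eaf"]]) if has_eaf else None
        if eaf is not None and not (0 < eaf < 1):
            counts.n_invalid += 1
            counts._bump("eaf_out_of_range")
            continue
        try:
            rec = SummaryRecord(
                variant_id=str(row_d[colmap["variant_id"]]),
                chrom=str(row_d[colmap["chrom"]]),
                pos=int(row_d[colmap["pos"]]),
                effect_allele=ea,
                other_allele=oa,
                beta=float(row_d[colmap["beta"]]),
                se=float(row_d[colmap["se"]]),
                pval=float(row_d[colmap["pval"]]),
                eaf=eaf,
                n=_coerce_float(row_d[colmap["n"]]) if has_n else None,
            )
            rec.validate()
        except (ValueError, TypeError) as exc:
            counts.n_invalid += 1
            counts._bump(type(exc).__name__)
            continue
        records.append(rec)
    counts.n_kept = len(records)
    if counts.n_read != counts.n_kept:
        logger.info(
            "%s: kept %d/%d rows (dropped: %s)", path, counts.n_kept, counts.n_read, counts.by_reason
        )
    return records, counts


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[SummaryRecord]:
    """As :func:`read_sumstats_counted`, returning the records only."""
    return read_sumstats_counted(path, column_map=column_map, sep=sep)[0]


def write_sumstats(
    records: Iterable[SummaryRecord],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> None:
    """Write records as a delimited table with the (possibly remapped) default headers."""
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    rows = [
        {
            colmap["variant_id"]: r.variant_id,
            colmap["chrom"]: r.chrom,
            colmap["pos"]: r.pos,
            colmap["effect_allele"]: r.effect_allele,
            colmap["other_allele"]: r.other_allele,
            colmap["eaf"]: r.eaf,
            colmap["beta"]: r.beta,
            colmap["se"]: r.se,
            colmap["pval"]: r.pval,
            colmap["n"]: r.n,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def is_palindromic(record: SummaryRecord) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    ea, oa = record.effect_allele, record.other_allele
    if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
        raise AlleleError(f"{record.variant_id}: non-ACGT allele pair ({ea!r}, {oa!r})")
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
) -> HarmonizedSet:
    """Align outcome records to the exposure's effect alleles.

    Variants present in both datasets (matched by ``variant_id``) are
    harmonized; palindromic variants are excluded, as are variants whose
    allele pairs cannot be reconciled by swapping and/or strand
    complementation.  The returned set carries the exposure's per-variant
    frequency and coordinates.

    Raises :class:`NoSharedVariantsError` when the datasets share no
    variants.
    """
    outcome_by_id = {r.variant_id: r for r in outcome}
    shared = [r for r in exposure if r.variant_id in outcome_by_id]
    if not shared:
        raise NoSharedVariantsError("exposure and outcome share no variant_ids")

    records: list[HarmonizedRecord] = []
    n_palindromic = 0
    n_incompatible = 0
    for exp in shared:
        out = outcome_by_id[exp.variant_id]
        if is_palindromic(exp) or is_palindromic(out):
            n_palindromic += 1
            continue
        ea, oa = out.effect_allele, out.other_allele
        exp_pair = (exp.effect_allele, exp.other_allele)
        if (ea, oa) != exp_pair and (oa, ea) != exp_pair:
            # try strand complement of the outcome's labels
            ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        if (ea, oa) == exp_pair:
            beta_out = out.beta
            eaf_out = out.eaf
        elif (oa, ea) == exp_pair:
            beta_out = -out.beta
            eaf_out = None if out.eaf is None else 1.0 - out.eaf
        else:
            n_incompatible += 1
            continue
        # frequency of the common effect allele: exposure's where available,
        # otherwise the outcome's after alignment
        eaf = exp.eaf if exp.eaf is not None else eaf_out
        records.append(
            HarmonizedRecord(
                variant_id=exp.variant_id,
                beta_exposure=exp.beta,
                se_exposure=exp.se,
                beta_outcome=beta_out,
                se_outcome=out.se,
                eaf=eaf,
                chrom=exp.chrom,
                pos=exp.pos,
            )
        )
    if n_palindromic or n_incompatible:
        logger.info(
            "harmonize: %d kept, %d palindromic removed, %d incompatible removed",
            len(records), n_palindromic, n_incompatible,
        )
    return HarmonizedSet(
        records=records,
        n_palindromic_removed=n_palindromic,
        n_incompatible_removed=n_incompatible,
    )
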