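"""Genetic-instrument selection for drug-target (cis) and trait-wide MR.

Instruments for a drug target are variants near the target gene that are
strongly associated with the exposure the drug modulates; they proxy
lifelong pharmacological perturbation of the target.  Selection applies,
in order:

1. exposure significance filter (default ``p < 5e-8``);
2. optional removal of variants already genome-wide significant for the
   outcome (to guard the exclusion-restriction assumption);
3. gene-region window filter (default gene span +/- 100 kb, inclusive);
4. removal of palindromic variants;
5. greedy LD pruning against a genotype reference panel (default
   ``r^2 < 0.3`` for cis instruments, ``r^2 < 0.001`` genome-wide).

Per-variant instrument strength is summarized by ``F = beta^2 / se^2``;
values of 10 or below are flagged as weak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from drugmr.sumstats import GeneRegion, SummaryRecord, is_palindromic

logger = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0


class PanelLookupError(KeyError):
    """A variant is absent from the reference panel."""


class DegenerateLDError(ValueError):
    """LD is undefined because a dosage column has zero variance."""


class EmptyInstrumentSetError(ValueError):
    """No variants survive instrument selection.

    ``stage`` names the filtering stage at which the candidate set became
    empty.
    """

    def __init__(self, stage: str):
        super().__init__(f"no instruments survive selection (emptied at stage {stage!r})")
        self.stage = stage


@dataclass
class ReferencePanel:
    """Genotype dosages for LD computation: individuals x variants.

    ``dosages[i, j]`` is the count of the alternate (effect) allele carried
    by individual ``i`` at variant ``j`` (0/1/2 for diploid genotypes).
    """

    variant_ids: list[str]
    dosages: np.ndarray

    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.variant_ids):
            raise ValueError("dosage matrix must be individuals x len(variant_ids)")
        self._index = {v: j for j, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[variant_id]]
        except KeyError:
            raise PanelLookupError(f"variant {variant_id!r} not in reference panel") from None

    @classmethod
    def from_vcf(cls, path: str | Path) -> "ReferencePanel":
        """Load biallelic SNP genotypes (GT field) from a VCF file."""
        from cyvcf2 import VCF

        ids: list[str] = []
        columns: list[np.ndarray] = []
        for var in VCF(str(path)):
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                continue
            gt = np.asarray(var.genotype.array())[:, :2]
            dos = np.where(gt < 0, np.nan, gt).sum(axis=1)
            # mean-impute the rare missing genotype so LD stays defined
            if np.isnan(dos).any():
                dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
            ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
            columns.append(dos.astype(float))
        if not ids:
            raise ValueError(f"{path}: no biallelic SNP records")
        return cls(variant_ids=ids, dosages=np.column_stack(columns))

    @classmethod
    def from_dosage_file(cls, path: str | Path) -> "ReferencePanel":
        """Load a whitespace-delimited dosage matrix with a variant-ID header row."""
        with open(path) as fh:
            header = fh.readline().split()
            if not header:
                raise ValueError(f"{path}: empty dosage file")
            rows = [[float(x) for x in line.split()] for line in fh if line.strip()]
        if not rows:
            raise ValueError(f"{path}: no individuals in dosage file")
        return cls(variant_ids=header, dosages=np.asarray(rows, dtype=float))


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of instrument selection.

    ``window_kb`` is the half-width added to each side of the gene region
    (1 kb = exactly 1000 bp, bounds inclusive); ``window_kb = 0`` together
    with ``region = None`` means genome-wide selection.
    """

    p_threshold: float = 5e-8
    window_kb: float = 100.0
    r2_threshold: float = 0.3
    region: GeneRegion | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must be in [0, 1]")

    @classmethod
    def cis(cls, region: GeneRegion, **kw) -> "SelectionConfig":
        """Cis preset: gene region +/- 100 kb, prune at r^2 < 0.3."""
        return replace(cls(region=region), **kw)

    @classmethod
    def genome_wide(cls, **kw) -> "SelectionConfig":
        """Genome-wide preset: no window, prune at r^2 < 0.001."""
        return replace(cls(window_kb=0.0, r2_threshold=0.001, region=None), **kw)


@dataclass
class InstrumentSet:
    """Selected exposure-side instruments with per-variant F-statistics."""

    records: list[SummaryRecord]
    f_stats: np.ndarray
    mean_f: float
    stage_counts: dict[str, int] = field(default_factory=dict)
    max_retained_r2: float = 0.0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_weak(self) -> int:
        return int(np.sum(self.f_stats <= WEAK_F_THRESHOLD))


def ld_r2(panel: ReferencePanel, id_a: str, id_b: str) -> float:
    """Squared Pearson correlation between two variants' dosage columns."""
    a = panel.column(id_a)
    b = panel.column(id_b)
    va = a - a.mean()
    vb = b - b.mean()
    den = float(va @ va) * float(vb @ vb)
    if den == 0.0:
        raise DegenerateLDError(f"zero dosage variance for {id_a!r} or {id_b!r}")
    r = float(va @ vb) / np.sqrt(den)
    return min(r * r, 1.0)


def _r2_matrix(panel: ReferencePanel, ids: Sequence[str]) -> np.ndarray:
    cols = np.column_stack([panel.column(v) for v in ids])
    sd = cols.std(axis=0)
    if np.any(sd == 0):
        bad = [v for v, s in zip(ids, sd) if s == 0]
        raise DegenerateLDError(f"zero dosage variance for {bad}")
    r = np.corrcoef(cols, rowvar=False)
    r = np.atleast_2d(r)
    return np.clip(r * r, 0.0, 1.0)


def greedy_prune(
    candidates: Sequence[SummaryRecord],
    panel: ReferencePanel,
    r2_threshold: float,
) -> list[SummaryRecord]:
    """Greedy LD pruning (clumping without secondary assignment).

    Repeatedly keep the remaining candidate with the smallest p-value
    (ties broken by lower genomic position) and discard every remaining
    candidate whose ``r^2`` with it is at or above ``r2_threshold``.
    Candidates absent from the panel are excluded with a warning.  The
    output preserves genomic order.
    """
    usable = [c for c in candidates if c.variant_id in panel]
    dropped = len(candidates) - len(usable)
    if dropped:
        logger.warning("greedy_prune: %d candidate(s) absent from reference panel, excluded", dropped)
    if not usable:
        return []
    ids = [c.variant_id for c in usable]
    r2 = _r2_matrix(panel, ids)
    order = sorted(range(len(usable)), key=lambda i: (usable[i].pval, usable[i].pos))
    alive = np.ones(len(usable), dtype=bool)
    kept: list[int] = []
    for i in order:
        if not alive[i]:
            continue
        kept.append(i)
        alive &= r2[i] < r2_threshold
        alive[i] = False
    kept.sort(key=lambda i: (usable[i].chrom, usable[i].pos))
    return [usable[i] for i in kept]


def f_statistic(record: SummaryRecord) -> float:
    """Per-variant instrument strength, F = beta^2 / se^2."""
    if not record.se > 0:
        raise ValueError(f"{record.variant_id}: se must be > 0")
    return (record.beta / record.se) ** 2


def is_weak(f: float) -> bool:
    """True when F does not exceed 10 (insufficient instrument strength)."""
    return f <= WEAK_F_THRESHOLD


def select_instruments(
    sumstats: Sequence[SummaryRecord],
    config: SelectionConfig,
    panel: ReferencePanel,
    outcome_sumstats: Sequence[SummaryRecord] | None = None,
) -> InstrumentSet:
    """Apply the full instrument-selection cascade and compute F-statistics.

    Raises :class:`EmptyInstrumentSetError` naming the first stage at which
    the candidate set became empty.
    """
    counts: dict[str, int] = {"input": len(sumstats)}

    current = [r for r in sumstats if r.pval < config.p_threshold]
    counts["exposure_p_filter"] = len(current)
    if not current:
        raise EmptyInstrumentSetError("exposure_p_filter")

    if outcome_sumstats is not None:
        out_p = {r.variant_id: r.pval for r in outcome_sumstats}
        current = [r for r in current if out_p.get(r.variant_id, 1.0) >= config.p_threshold]
        counts["outcome_overlap_filter"] = len(current)
        if not current:
            raise EmptyInstrumentSetError("outcome_overlap_filter")

    if config.region is not None:
        lo = config.region.start - config.window_kb * 1000.0
        hi = config.region.end + config.window_kb * 1000.0
        chrom = _norm_chrom(config.region.chrom)
        current = [r for r in current if _norm_chrom(r.chrom) == chrom and lo <= r.pos <= hi]
        counts["window_filter"] = len(current)
        if not current:
            raise EmptyInstrumentSetError("window_filter")

    current = [r for r in current if not is_palindromic(r)]
    counts["palindromic_filter"] = len(current)
    if not current:
        raise EmptyInstrumentSetError("palindromic_filter")

    current = greedy_prune(current, panel, config.r2_threshold)
    counts["ld_prune"] = len(current)
    if not current:
        raise EmptyInstrumentSetError("ld_prune")

    f_stats = np.array([f_statistic(r) for r in current])
    max_r2 = 0.0
    if len(current) > 1:
        r2 = _r2_matrix(panel, [r.variant_id for r in current])
        iu = np.triu_indices(len(current), k=1)
        max_r2 = float(r2[iu].max())
        if max_r2 > 0:
            logger.info("select_instruments: maximum retained pairwise r^2 = %.4f", max_r2)
    n_weak = int(np.sum(f_stats <= WEAK_F_THRESHOLD))
    if n_weak:
        logger.warning("select_instruments: %d instrument(s) with F <= 10 (weak)", n_weak)
    logger.info("select_instruments: stage counts %s", counts)
    return InstrumentSet(
        records=current,
        f_stats=f_stats,
        mean_f=float(f_stats.mean()),
        stage_counts=counts,
        max_retained_r2=max_r2,
    )


def _norm_chrom(chrom: str) -> str:
    c = str(chrom).lower()
    return c[3:] if c.startswith("chr") else c
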