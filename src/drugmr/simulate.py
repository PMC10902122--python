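"""Synthetic reference panels and multi-trait GWAS summary statistics.

The generator emulates the statistical structure a two-sample drug-target
MR study assumes: a cis gene region whose variants causally raise or lower
a standardized quantitative exposure, block LD (first-order autoregressive
latent correlation within blocks, independence across blocks), a binary
downstream outcome generated on the log-odds scale with a configurable
causal effect and optional balanced/directional pleiotropy, an optional
quantitative mediator on the exposure-outcome path, and strictly
non-overlapping cohorts per trait (separate RNG streams per cohort).

Marginal per-variant summary statistics are produced the way a GWAS would:
simple linear regression per variant for quantitative traits and
per-variant logistic regression (vectorized Newton-Raphson) for the binary
outcome, yielding beta/se/p/eaf/n records.

Everything is deterministic given ``ScenarioConfig.seed``; the realized
ground truth is emitted alongside the data so downstream estimates can be
scored.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from drugmr.instruments import ReferencePanel
from drugmr.sumstats import GeneRegion, SummaryRecord

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class Pleiotropy:
    """Direct variant-to-outcome effects violating exclusion restriction.

    ``mode``: ``none``, ``balanced`` (effects uniform on
    [-magnitude, +magnitude]) or ``directional`` (uniform on
    [0, 2*magnitude], mean ``magnitude``).  ``fraction`` is the share of
    exposure-causal variants that receive a pleiotropic effect.
    """

    mode: str = "none"
    magnitude: float = 0.0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ValueError("pleiotropy mode must be none|balanced|directional")
        if not (0 <= self.fraction <= 1):
            raise ValueError("pleiotropy fraction must be in [0, 1]")


@dataclass(frozen=True)
class MediatorChain:
    """Exposure -> mediator -> outcome path: M = b1*E + own genetics,
    logit(Y) gains ``direct*E + b2*M``."""

    b1: float
    b2: float
    direct: float

    @property
    def total(self) -> float:
        return self.direct + self.b1 * self.b2

    @property
    def proportion(self) -> float:
        return self.b1 * self.b2 / self.total


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults describe the desk-scale study: 200 variants in 4 LD blocks
    (latent AR(1) rho = 0.9), 10 causal cis variants explaining 10% of a
    standardized exposure, reference panel of 2,000 individuals, and
    10,000 individuals per (non-overlapping) GWAS cohort with a 10% case
    fraction for the binary outcome.
    """

    n_variants: int = 200
    n_blocks: int = 4
    within_block_rho: float = 0.9
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_ref: int = 2000
    n_exposure: int = 10000
    n_outcome: int = 10000
    n_mediator: int = 10000
    causal_variants: tuple[tuple[int, float], ...] | None = None
    h2_exposure: float = 0.1
    causal_effect_b: float = 0.0
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    mediator_chain: MediatorChain | None = None
    mediator_causal_variants: tuple[tuple[int, float], ...] | None = None
    h2_mediator: float = 0.1
    case_fraction: float = 0.1
    palindromic_fraction: float = 0.0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_spacing: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_variants, self.n_blocks, self.n_ref, self.n_exposure, self.n_outcome) < 1:
            raise ValueError("sizes must be positive")
        if not (0 <= self.within_block_rho < 1):
            raise ValueError("within_block_rho must be in [0, 1)")
        if not (0 <= self.h2_exposure < 1):
            raise ValueError("h2_exposure must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0, 1)")
        for idx, _ in self.resolved_causal_variants():
            if not (0 <= idx < self.n_variants):
                raise ValueError(f"causal index {idx} out of range")

    def resolved_causal_variants(self) -> tuple[tuple[int, float], ...]:
        """Explicit causal variants, or the default layout: 10 variants
        evenly spread over the region with linearly varying weights."""
        if self.causal_variants is not None:
            return tuple((int(i), float(w)) for i, w in self.causal_variants)
        k = min(10, self.n_variants)
        idx = np.unique(np.round(np.linspace(0, self.n_variants - 1, k)).astype(int))
        weights = np.linspace(0.5, 1.5, len(idx))
        return tuple((int(i), float(w)) for i, w in zip(idx, weights))

    def resolved_mediator_causal_variants(self) -> tuple[tuple[int, float], ...]:
        """Mediator-specific causal variants: explicit, or 10 variants
        chosen away from the exposure's causal set."""
        if self.mediator_causal_variants is not None:
            return tuple((int(i), float(w)) for i, w in self.mediator_causal_variants)
        exp_idx = {i for i, _ in self.resolved_causal_variants()}
        free = [j for j in range(self.n_variants) if j not in exp_idx]
        if not free:
            raise ValueError("no variants left for mediator-specific effects")
        k = min(10, len(free))
        picks = np.unique(np.round(np.linspace(0, len(free) - 1, k)).astype(int))
        return tuple((int(free[p]), 1.0) for p in picks)


@dataclass
class VariantMeta:
    """Per-variant annotation shared by panel and all cohorts."""

    ids: list[str]
    chrom: str
    positions: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    mafs: np.ndarray
    block_starts: np.ndarray


@dataclass
class ScenarioTruth:
    """Realized generative parameters, sufficient to score recovery."""

    seed: int
    causal_indices: list[int]
    gamma: list[float]
    realized_h2_exposure: float
    causal_effect_b: float
    gene_region: dict
    pleiotropy_indices: list[int] = field(default_factory=list)
    pleiotropy_effects: list[float] = field(default_factory=list)
    mediator_indices: list[int] = field(default_factory=list)
    delta: list[float] = field(default_factory=list)
    b1: float | None = None
    b2: float | None = None
    direct: float | None = None
    true_b0: float | None = None
    true_proportion: float | None = None
    realized_case_fraction: float | None = None
    child_seeds: dict = field(default_factory=dict)

    def region(self) -> GeneRegion:
        g = self.gene_region
        return GeneRegion(gene=g["gene"], chrom=g["chrom"], start=g["start"], end=g["end"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedStudy:
    """Output bundle of :func:`simulate_gwas`."""

    exposure: list[SummaryRecord]
    outcome: list[SummaryRecord]
    mediator: list[SummaryRecord] | None
    truth: ScenarioTruth


# ---------------------------------------------------------------------------
# RNG stream bookkeeping: one spawned child per purpose, so cohorts are
# independent by construction and any subset can be regenerated.

_STREAMS = ("meta", "effects", "panel", "exposure", "outcome", "mediator")


def _streams(config: ScenarioConfig) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _stream_keys(config: ScenarioConfig) -> dict[str, int]:
    children = np.random.SeedSequence(config.seed).spawn(len(_STREAMS))
    return {name: int(child.generate_state(1)[0]) for name, child in zip(_STREAMS, children)}


def variant_meta(config: ScenarioConfig) -> VariantMeta:
    """Deterministic per-variant annotation (positions, alleles, MAFs, blocks)."""
    rng = _streams(config)["meta"]
    m = config.n_variants
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    pal = rng.random(m) < config.palindromic_fraction
    pair_choice = rng.integers(0, 8, size=m)
    pal_choice = rng.integers(0, 4, size=m)
    ea, oa = [], []
    for j in range(m):
        a, b = _PALINDROMIC_PAIRS[pal_choice[j]] if pal[j] else _NONPALINDROMIC_PAIRS[pair_choice[j]]
        ea.append(a)
        oa.append(b)
    positions = config.pos_start + config.pos_spacing * np.arange(m)
    block_size = max(1, m // config.n_blocks)
    block_starts = np.arange(0, m, block_size)[: config.n_blocks]
    return VariantMeta(
        ids=[f"rs{j + 1}" for j in range(m)],
        chrom=config.chrom,
        positions=positions,
        effect_alleles=ea,
        other_alleles=oa,
        mafs=mafs,
        block_starts=block_starts,
    )


def _haplotypes(rng: np.random.Generator, meta: VariantMeta, n_hap: int, rho: float) -> np.ndarray:
    """Haplotypes by thresholding blockwise AR(1) latent Gaussians at the
    per-variant MAF quantile (so the effect allele IS the minor allele)."""
    m = len(meta.ids)
    z = rng.standard_normal((n_hap, m))
    x = np.empty_like(z)
    starts = set(int(s) for s in meta.block_starts)
    innov = math.sqrt(1.0 - rho * rho)
    for j in range(m):
        if j in starts:
            x[:, j] = z[:, j]
        else:
            x[:, j] = rho * x[:, j - 1] + innov * z[:, j]
    thresholds = norm.ppf(meta.mafs)
    return (x < thresholds[None, :]).astype(np.float64)


def _dosages(rng: np.random.Generator, meta: VariantMeta, n_ind: int, rho: float) -> np.ndarray:
    hap = _haplotypes(rng, meta, 2 * n_ind, rho)
    return hap[0::2] + hap[1::2]


def simulate_panel(config: ScenarioConfig, meta: VariantMeta | None = None) -> ReferencePanel:
    """Genotype reference panel drawn from the scenario's LD process."""
    meta = meta or variant_meta(config)
    rng = _streams(config)["panel"]
    dos = _dosages(rng, meta, config.n_ref, config.within_block_rho)
    if np.any(dos.std(axis=0) == 0):
        raise RuntimeError("generated a monomorphic panel column; increase n_ref or MAF range")
    return ReferencePanel(variant_ids=list(meta.ids), dosages=dos)


# ---------------------------------------------------------------------------
# marginal association scans


def marginal_linear(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regression of ``y`` on genotype dosage.

    Returns (beta, se, pval); p-values from the normal approximation, as
    GWAS summary files report them.
    """
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = syy - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / (n - 2)
        se = np.sqrt(np.where(sxx > 0, sigma2 / np.where(sxx > 0, sxx, 1.0), np.inf))
    pval = 2.0 * norm.sf(np.abs(beta) / se)
    return beta, se, np.clip(pval, np.finfo(float).tiny, 1.0)


def marginal_logistic(
    g: np.ndarray, y: np.ndarray, max_iter: int = 40, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column logistic regression (intercept + dosage), vectorized
    Newton-Raphson across columns.  Returns (beta, se, pval) for the
    dosage coefficient; Wald p-values from the normal approximation.
    """
    n, m = g.shape
    ybar = float(y.mean())
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError("degenerate binary outcome: all cases or all controls")
    yf = y.astype(float)
    a = np.full(m, logit(ybar))
    b = np.zeros(m)
    g2 = g * g
    haa = hab = hbb = det = None
    for _ in range(max_iter):
        eta = a[None, :] + g * b[None, :]
        p = expit(eta)
        w = p * (1.0 - p)
        r = yf[:, None] - p
        ua = r.sum(axis=0)
        ub = np.einsum("ij,ij->j", g, r)
        haa = w.sum(axis=0)
        hab = np.einsum("ij,ij->j", g, w)
        hbb = np.einsum("ij,ij->j", g2, w)
        det = haa * hbb - hab * hab
        da = (hbb * ua - hab * ub) / det
        db = (haa * ub - hab * ua) / det
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    se = np.sqrt(haa / det)
    pval = 2.0 * norm.sf(np.abs(b) / se)
    return b, se, np.clip(pval, np.finfo(float).tiny, 1.0)


def _records(
    meta: VariantMeta,
    beta: np.ndarray,
    se: np.ndarray,
    pval: np.ndarray,
    eaf: np.ndarray,
    n: int,
) -> list[SummaryRecord]:
    return [
        SummaryRecord(
            variant_id=meta.ids[j],
            chrom=meta.chrom,
            pos=int(meta.positions[j]),
            effect_allele=meta.effect_alleles[j],
            other_allele=meta.other_alleles[j],
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(pval[j]),
            eaf=float(np.clip(eaf[j], 1e-6, 1 - 1e-6)),
            n=n,
        )
        for j in range(len(meta.ids))
    ]


def _dosage_cov(meta: VariantMeta, rho: float, i: int, j: int) -> float:
    """Population covariance of two dosage columns under the latent AR(1)
    threshold model (bivariate-normal orthant probability)."""
    from scipy.stats import multivariate_normal

    if i == j:
        p = meta.mafs[i]
        return 2.0 * p * (1.0 - p)
    block_i = int(np.searchsorted(meta.block_starts, i, side="right")) - 1
    block_j = int(np.searchsorted(meta.block_starts, j, side="right")) - 1
    if block_i != block_j or rho == 0.0:
        return 0.0
    r = rho ** abs(i - j)
    t_i, t_j = norm.ppf(meta.mafs[i]), norm.ppf(meta.mafs[j])
    joint = multivariate_normal.cdf([t_i, t_j], mean=[0.0, 0.0],
                                    cov=[[1.0, r], [r, 1.0]])
    return 2.0 * (float(joint) - meta.mafs[i] * meta.mafs[j])


def _scaled_effects(
    pairs: Sequence[tuple[int, float]],
    meta: VariantMeta,
    rho: float,
    h2: float,
) -> np.ndarray:
    """Per-allele effects scaled so the population explained variance is h2,
    accounting for LD among the causal variants."""
    m = len(meta.ids)
    gamma = np.zeros(m)
    if h2 == 0 or not pairs:
        return gamma
    idx = [i for i, _ in pairs]
    w = np.array([wt for _, wt in pairs], dtype=float)
    k = len(idx)
    sigma = np.empty((k, k))
    for a in range(k):
        for b in range(a, k):
            sigma[a, b] = sigma[b, a] = _dosage_cov(meta, rho, idx[a], idx[b])
    var_total = float(w @ sigma @ w)
    gamma[np.array(idx)] = w * math.sqrt(h2 / var_total)
    return gamma


def _solve_intercept(lp: np.ndarray, k: float) -> float:
    f = lambda a: float(expit(a + lp).mean()) - k
    return brentq(f, -35.0, 35.0, xtol=1e-10)


def simulate_gwas(config: ScenarioConfig, meta: VariantMeta | None = None) -> SimulatedStudy:
    """Draw independent cohorts and return their marginal summary statistics.

    The exposure cohort yields linear-regression statistics for the
    standardized exposure; the outcome cohort yields logistic-regression
    statistics for the binary outcome (logit intercept solved so the
    expected case fraction matches the configuration); an optional
    mediator cohort yields linear statistics for the mediator.  Cohorts
    never share individuals or RNG streams.
    """
    meta = meta or variant_meta(config)
    streams = _streams(config)
    m = config.n_variants
    rho = config.within_block_rho
    causal = config.resolved_causal_variants()
    gamma = _scaled_effects(causal, meta, rho, config.h2_exposure)
    noise_sd = math.sqrt(1.0 - config.h2_exposure)

    chain = config.mediator_chain
    delta = np.zeros(m)
    med_causal: tuple[tuple[int, float], ...] = ()
    if chain is not None:
        med_causal = config.resolved_mediator_causal_variants()
        delta = _scaled_effects(med_causal, meta, rho, config.h2_mediator)
        resid_m = 1.0 - chain.b1**2 - config.h2_mediator
        if resid_m <= 0:
            raise ValueError("mediator chain infeasible: b1^2 + h2_mediator must be < 1")
        med_noise_sd = math.sqrt(resid_m)

    # pleiotropy assignment (effects stream, so cohort draws stay untouched)
    rng_eff = streams["effects"]
    alpha = np.zeros(m)
    pl = config.pleiotropy
    pl_idx: np.ndarray = np.array([], dtype=int)
    if pl.mode != "none" and pl.magnitude > 0 and causal:
        cidx = np.array([i for i, _ in causal])
        n_pl = int(round(pl.fraction * len(cidx)))
        pl_idx = np.sort(rng_eff.choice(cidx, size=n_pl, replace=False))
        if pl.mode == "directional":
            alpha[pl_idx] = rng_eff.uniform(0.0, 2.0 * pl.magnitude, size=n_pl)
        else:
            alpha[pl_idx] = rng_eff.uniform(-pl.magnitude, pl.magnitude, size=n_pl)

    # exposure cohort
    rng_e = streams["exposure"]
    g_e = _dosages(rng_e, meta, config.n_exposure, rho)
    gv_e = g_e @ gamma
    e_pheno = gv_e + noise_sd * rng_e.standard_normal(config.n_exposure)
    be, se_e, pe = marginal_linear(g_e, e_pheno)
    exposure_records = _records(meta, be, se_e, pe, g_e.mean(axis=0) / 2.0, config.n_exposure)
    realized_h2 = float(np.var(gv_e) / np.var(e_pheno)) if config.h2_exposure > 0 else 0.0

    # mediator cohort
    mediator_records = None
    if chain is not None:
        rng_m = streams["mediator"]
        g_m = _dosages(rng_m, meta, config.n_mediator, rho)
        e_m = g_m @ gamma + noise_sd * rng_m.standard_normal(config.n_mediator)
        m_pheno = chain.b1 * e_m + g_m @ delta + med_noise_sd * rng_m.standard_normal(config.n_mediator)
        bm, se_m, pm = marginal_linear(g_m, m_pheno)
        mediator_records = _records(meta, bm, se_m, pm, g_m.mean(axis=0) / 2.0, config.n_mediator)

    # outcome cohort
    rng_o = streams["outcome"]
    g_o = _dosages(rng_o, meta, config.n_outcome, rho)
    e_o = g_o @ gamma + noise_sd * rng_o.standard_normal(config.n_outcome)
    if chain is not None:
        m_o = chain.b1 * e_o + g_o @ delta + med_noise_sd * rng_o.standard_normal(config.n_outcome)
        lp = chain.direct * e_o + chain.b2 * m_o
    else:
        lp = config.causal_effect_b * e_o
    if np.any(alpha != 0):
        lp = lp + g_o @ alpha
    a0 = _solve_intercept(lp, config.case_fraction)
    y = (rng_o.random(config.n_outcome) < expit(a0 + lp)).astype(np.int8)
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == config.n_outcome:
        raise RuntimeError("degenerate outcome: all cases or all controls")
    bo, se_o, po = marginal_logistic(g_o, y)
    outcome_records = _records(meta, bo, se_o, po, g_o.mean(axis=0) / 2.0, config.n_outcome)

    cidx_list = [int(i) for i, _ in causal]
    region = _gene_region(meta, cidx_list)
    truth = ScenarioTruth(
        seed=config.seed,
        causal_indices=cidx_list,
        gamma=[float(gamma[i]) for i in cidx_list],
        realized_h2_exposure=realized_h2,
        causal_effect_b=(chain.total if chain is not None else config.causal_effect_b),
        gene_region={"gene": "SYNTH1", "chrom": meta.chrom,
                     "start": region.start, "end": region.end},
        pleiotropy_indices=[int(i) for i in pl_idx],
        pleiotropy_effects=[float(alpha[i]) for i in pl_idx],
        mediator_indices=[int(i) for i, _ in med_causal],
        delta=[float(delta[i]) for i, _ in med_causal],
        b1=chain.b1 if chain else None,
        b2=chain.b2 if chain else None,
        direct=chain.direct if chain else None,
        true_b0=chain.total if chain else None,
        true_proportion=chain.proportion if chain else None,
        realized_case_fraction=n_cases / config.n_outcome,
        child_seeds=_stream_keys(config),
    )
    return SimulatedStudy(
        exposure=exposure_records,
        outcome=outcome_records,
        mediator=mediator_records,
        truth=truth,
    )


def _gene_region(meta: VariantMeta, causal_indices: list[int]) -> GeneRegion:
    lo = int(meta.positions[min(causal_indices)])
    hi = int(meta.positions[max(causal_indices)])
    return GeneRegion(gene="SYNTH1", chrom=meta.chrom, start=lo, end=hi)


def coloc_scenario(
    config: ScenarioConfig,
    shared: bool,
    h2: float = 0.01,
    causal1: int | None = None,
    causal2: int | None = None,
) -> tuple[list[SummaryRecord], list[SummaryRecord], ScenarioTruth]:
    """Two quantitative traits in one window, sharing (or not) a causal variant.

    Each trait's single causal variant explains ``h2`` of its variance
    (default 1%).  When ``shared`` is false the two causal variants sit in
    different LD blocks, so their r^2 is near zero.  Trait 1 uses the
    exposure cohort stream and sample size, trait 2 the outcome ones.
    """
    meta = variant_meta(config)
    streams = _streams(config)
    m = config.n_variants
    if causal1 is None:
        causal1 = m // 2 - max(1, m // 8)
    if causal2 is None:
        causal2 = causal1 if shared else min(m - 1, m // 2 + max(1, m // 8))
    out = []
    for rng, n, cidx in (
        (streams["exposure"], config.n_exposure, causal1),
        (streams["outcome"], config.n_outcome, causal2),
    ):
        g = _dosages(rng, meta, n, config.within_block_rho)
        gamma = _scaled_effects([(cidx, 1.0)], meta, config.within_block_rho, h2)
        y = g @ gamma + math.sqrt(1.0 - h2) * rng.standard_normal(n)
        beta, se, pval = marginal_linear(g, y)
        out.append(_records(meta, beta, se, pval, g.mean(axis=0) / 2.0, n))
    region = _gene_region(meta, [causal1, causal2])
    truth = ScenarioTruth(
        seed=config.seed,
        causal_indices=[int(causal1), int(causal2)],
        gamma=[h2, h2],
        realized_h2_exposure=h2,
        causal_effect_b=0.0,
        gene_region={"gene": "SYNTH1", "chrom": meta.chrom,
                     "start": region.start, "end": region.end},
        child_seeds=_stream_keys(config),
    )
    return out[0], out[1], truth


def write_panel_vcf(panel: ReferencePanel, meta: VariantMeta, path: str | Path) -> None:
    """Write the panel as a minimal uncompressed VCF (GT-only, unphased)."""
    n = panel.n_individuals
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={meta.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"I{i + 1}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j, vid in enumerate(panel.variant_ids):
            dos = panel.dosages[:, j].astype(int)
            gts = "\t".join(gt_map[int(d)] for d in dos)
            fh.write(
                f"{meta.chrom}\t{int(meta.positions[j])}\t{vid}\t{meta.other_alleles[j]}"
                f"\t{meta.effect_alleles[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
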